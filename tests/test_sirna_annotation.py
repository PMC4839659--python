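import math
import random
from fractions import Fraction

import pytest

from srnakit.config import Thresholds
from srnakit.genome_index import Hit, build_index, map_library
from srnakit.io_formats import GeneModel
from srnakit.sirna_annotation import (FEATURE_DIM, annotate_hit_context,
                                      fit_pirna_model, kmer_features,
                                      natsirna_calls, phasing_pvalue,
                                      pirna_classify, positional_bias,
                                      rasirna_calls, simulate_background,
                                      simulate_pirna_like, tasirna_scan)


# --- ra-siRNA --------------------------------------------------------------

def _hit(scaf, s, e, strand="+", read=None):
    return Hit(scaf, s, e, strand, read or "A" * (e - s))


def test_contained_hit_flagged():
    hits = {"r1": [_hit("s", 110, 130)]}
    flagged, summary = rasirna_calls(hits, [("s", 100, 200)])
    assert len(flagged) == 1
    assert summary.unique_fraction == 1.0


def test_straddling_hit_not_flagged():
    hits = {"r1": [_hit("s", 95, 115)]}
    flagged, summary = rasirna_calls(hits, [("s", 100, 200)])
    assert flagged == []
    assert summary.n_unique_repeat == 0


def test_repeat_fraction_on_synthetic(pipeline42, thresholds):
    ds = pipeline42.dataset
    counts = {r.sequence: r.count
              for r in pipeline42.unique_reads}
    _, summary = rasirna_calls(pipeline42.hits_by_read, ds.repeats, counts)
    # reads were planted inside repeats; the call recovers a sane fraction
    planted = {rec.sequence for rec, o in
               zip(ds.reads.records, ds.reads.origins)
               if o is not None and ds.genome.truth[o].kind == "repeat_copy"}
    called = summary.n_unique_repeat
    assert called >= 0.9 * len(planted & set(pipeline42.hits_by_read))


# --- phasing statistic -----------------------------------------------------

def test_phasing_k0_certain():
    assert phasing_pvalue(0, 5, 10, 100) == 1.0


def test_phasing_small_exact():
    # C(2,2)*C(8,0)/C(10,2) = 1/45
    assert phasing_pvalue(2, 2, 2, 10) == pytest.approx(1 / 45)


def test_phasing_inconsistent_counts():
    with pytest.raises(ValueError):
        phasing_pvalue(5, 4, 10, 100)
    with pytest.raises(ValueError):
        phasing_pvalue(1, 2, 200, 100)


def _phasing_oracle(k, n, K, N):
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if n - x <= N - K:
            total += Fraction(math.comb(K, x) * math.comb(N - K, n - x),
                              math.comb(N, n))
    return total


def test_phasing_matches_rational_oracle():
    rng = random.Random(2024)
    for _ in range(300):
        N = rng.randint(2, 60)
        K = rng.randint(1, N)
        n = rng.randint(1, N)
        k = rng.randint(0, min(n, K))
        expected = float(_phasing_oracle(k, n, K, N))
        assert phasing_pvalue(k, n, K, N) == pytest.approx(expected,
                                                           rel=1e-9), \
            (k, n, K, N)


def test_phasing_monotone_in_k():
    prev = 1.1
    for k in range(0, 11):
        p = phasing_pvalue(k, 15, 22, 462)
        assert p <= prev + 1e-12
        prev = p


# --- ta-siRNA scan ---------------------------------------------------------

def test_tasirna_planted_locus(thresholds):
    # 9 in-register sense reads, nothing else
    hits = [_hit("s", 1000 + 21 * k, 1021 + 21 * k) for k in range(9)]
    loci = tasirna_scan(hits, thresholds)
    assert len(loci) == 1
    locus = loci[0]
    assert locus.k == 9 and locus.n == 9
    assert locus.p_value < thresholds.phase_alpha
    assert locus.N == 2 * thresholds.phase_window
    assert locus.K == 2 * (thresholds.phase_window // thresholds.phase_len)


def test_tasirna_requires_phase_length(thresholds):
    with pytest.raises(ValueError):
        tasirna_scan([_hit("s", 0, 25)], thresholds)


def test_tasirna_empty(thresholds):
    assert tasirna_scan([], thresholds) == []


def test_tasirna_antisense_register(thresholds):
    # sense anchor + antisense reads at the +2 offset all count in-phase
    hits = [_hit("s", 1000, 1021, "+")]
    hits += [_hit("s", 1002 + 21 * k, 1023 + 21 * k, "-") for k in range(1, 8)]
    loci = tasirna_scan(hits, thresholds)
    assert len(loci) == 1
    assert loci[0].k == 8


def test_tasirna_type_one_error_small(thresholds):
    # uniform occupancy: per-window false-positive rate stays at or
    # below the nominal alpha (the full 10k-window run lives in the
    # acceptance suite)
    rng = random.Random(7)
    n_windows, n_occupied = 2000, 15
    N, K = 2 * 231, 2 * 11
    false = 0
    for _ in range(n_windows):
        occ = rng.sample(range(N), n_occupied)
        k = sum(1 for p in occ
                if (p < 231 and p % 21 == 0)
                or (p >= 231 and (p - 231) % 21 == 2))
        if k and phasing_pvalue(k, n_occupied, K, N) <= thresholds.phase_alpha:
            false += 1
    se = math.sqrt(0.001 * 0.999 / n_windows)
    assert false / n_windows <= 0.001 + 3 * se


# --- nat-siRNA -------------------------------------------------------------

NAT_GENES = [
    GeneModel("gA", "gA.t", "s", "+", [(100, 400)]),
    GeneModel("gB", "gB.t", "s", "-", [(375, 700)]),  # overlap 25
    GeneModel("gC", "gC.t", "s", "+", [(1000, 1300)]),
    GeneModel("gD", "gD.t", "s", "-", [(1276, 1600)]),  # overlap 24
]


def test_nat_pairs_overlap_threshold(thresholds):
    _, pairs = natsirna_calls({}, NAT_GENES, thresholds)
    assert [(a, b) for a, b, _ in pairs] == [("gA", "gB")]
    assert pairs[0][2] == 25


def test_antisense_exon_hit_flagged(thresholds):
    hits = {"r": [_hit("s", 150, 171, "-")]}
    flagged, _ = natsirna_calls(hits, NAT_GENES, thresholds)
    assert len(flagged) == 1


def test_sense_exon_hit_not_flagged(thresholds):
    hits = {"r": [_hit("s", 150, 171, "+")]}
    flagged, _ = natsirna_calls(hits, NAT_GENES, thresholds)
    assert flagged == []


# --- per-read context ------------------------------------------------------

CTX_GENES = [GeneModel("g", "g.t", "s", "+", [(100, 200), (400, 500)])]


def test_context_most_frequent_feature_rule():
    hits = {"r": [_hit("s", 120, 140, "+"), _hit("s", 150, 170, "+"),
                  _hit("s", 900, 920, "+")]}
    labels, summary = annotate_hit_context(hits, CTX_GENES)
    assert labels["r"] == "sense_exon"
    assert summary["sense_exon"] == 1


def test_context_only_intergenic():
    hits = {"r": [_hit("s", 900, 920), _hit("s", 950, 970)]}
    labels, _ = annotate_hit_context(hits, CTX_GENES)
    assert labels["r"] == "intergenic"


def test_context_tie_lexicographic():
    # one antisense-exon hit and one sense-intron hit: tie at count 1,
    # lexicographically first label wins
    hits = {"r": [_hit("s", 120, 140, "-"), _hit("s", 250, 270, "+")]}
    labels, _ = annotate_hit_context(hits, CTX_GENES)
    assert labels["r"] == "antisense_exon"


def test_context_intron_strandedness():
    labels, _ = annotate_hit_context({"r": [_hit("s", 250, 270, "-")]},
                                     CTX_GENES)
    assert labels["r"] == "antisense_intron"


# --- piRNA classifier ------------------------------------------------------

def test_feature_dimension():
    assert FEATURE_DIM == 4 + 16 + 64 + 256 + 1024 == 1364
    assert kmer_features("A" * 26).shape == (1364,)


def test_separable_toy_sets():
    pos = ["A" * 26 + "G", "A" * 27, "A" * 25 + "GA", "A" * 28]
    neg = ["G" * 26 + "A", "G" * 27, "G" * 25 + "AG", "G" * 28]
    model = fit_pirna_model(pos, neg)
    assert all(model.classify(s) for s in pos)
    assert not any(model.classify(s) for s in neg)


def test_pirna_held_out_accuracy():
    pos = simulate_pirna_like(500, seed=1)
    neg = simulate_background(500, seed=2)
    train_p, test_p = pos[:350], pos[350:]
    train_n, test_n = neg[:350], neg[350:]
    results = pirna_classify(train_p, train_n, test_p + test_n)
    correct = sum(1 for (_, _, lab) in results[:len(test_p)] if lab)
    correct += sum(1 for (_, _, lab) in results[len(test_p):] if not lab)
    assert correct / (len(test_p) + len(test_n)) >= 0.9


def test_pirna_query_length_enforced():
    with pytest.raises(ValueError):
        pirna_classify(["A" * 26], ["G" * 26], ["A" * 10])


def test_pirna_training_sets_required():
    with pytest.raises(ValueError):
        fit_pirna_model([], ["G" * 26])


def test_pirna_deterministic():
    pos = simulate_pirna_like(50, seed=3)
    neg = simulate_background(50, seed=4)
    m1 = fit_pirna_model(pos, neg)
    m2 = fit_pirna_model(pos, neg)
    assert m1.threshold == m2.threshold
    assert m1.score("T" * 28) == m2.score("T" * 28)


# --- positional bias -------------------------------------------------------

def test_all_u_start():
    assert positional_bias(["TAA", "TCC", "TGG"], 1, "U") == 1.0


def test_empty_set_warns():
    with pytest.warns(UserWarning):
        assert positional_bias([], 1, "U") == 0.0


def test_planted_bias_recovered():
    rng = random.Random(0)
    seqs = [("T" if rng.random() < 0.35 else "G") + "A" * 25
            for _ in range(1000)]
    assert positional_bias(seqs, 1, "T") == pytest.approx(0.35, abs=0.03)


def test_position_beyond_length_excluded():
    assert positional_bias(["AAA", "AAAAAAAAAA"], 10, "A") == 1.0
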