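import pytest

from srnakit.config import Thresholds
from srnakit.genome_index import Hit
from srnakit.mirna_discovery import (MiRNACandidate, call_mirnas,
                                     classify_context, evaluate_hairpin,
                                     mfe_screen, reference_candidates,
                                     scan_windows, suffix_prefix_overlap,
                                     summarize_candidates)
from srnakit.io_formats import GeneModel
from srnakit.read_processing import UniqueRead, revcomp
from srnakit.synthetic_data import build_genome, plant_feature, simulate_reads


# --- window scan -----------------------------------------------------------

def test_thirteen_window_lengths(thresholds):
    lengths = range(thresholds.window_min, thresholds.window_max + 1,
                    thresholds.window_step)
    assert len(list(lengths)) == 13


def test_scan_windows_lengths_and_placements(thresholds):
    genome = {"s": "ACGT" * 2000}
    hit = Hit("s", 4000, 4021, "+", genome["s"][4000:4021])
    wins = scan_windows(hit, genome, thresholds)
    lengths = {w.end - w.start for w in wins}
    assert lengths == set(range(60, 301, 20))
    per_len = [w for w in wins if w.end - w.start == 100]
    assert 1 <= len(per_len) <= 3
    for w in wins:
        a, b = w.mature_span
        assert w.sequence[a:b] == hit.read


def test_scan_windows_clipped_at_scaffold_start(thresholds):
    genome = {"s": "ACGT" * 500}
    hit = Hit("s", 5, 26, "+", genome["s"][5:26])
    wins = scan_windows(hit, genome, thresholds)
    assert wins  # shifted placements survive
    assert all(w.start >= 0 and w.end <= len(genome["s"]) for w in wins)


def test_scan_windows_minus_strand(thresholds):
    genome = {"s": "ACGTTGCATGCCGATTGGCA" * 100}
    hit = Hit("s", 500, 521, "-", revcomp(genome["s"][500:521]))
    for w in scan_windows(hit, genome, thresholds):
        a, b = w.mature_span
        assert w.sequence == revcomp(genome["s"][w.start:w.end])
        assert w.sequence[a:b] == hit.read


# --- hairpin evaluation ----------------------------------------------------

def test_mfe_screen_worked_example(thresholds):
    assert thresholds.mfe_coeff * 100 == pytest.approx(-35.0)
    assert not mfe_screen(-34.9, 100, thresholds)
    assert mfe_screen(-35.1, 100, thresholds)
    assert not mfe_screen(-35.0, 100, thresholds)  # strict inequality


def test_planted_hairpin_passes(thresholds):
    genome = build_genome(1, 5000, 0.6, seed=3)
    feat = plant_feature(genome, "mirna_hairpin", {"mature_count": 5}, seed=4,
                        thresholds=thresholds)
    hit = Hit(feat.scaffold, feat.start,
              feat.start + len(feat.payload["mature_seq"]), "+",
              feat.payload["mature_seq"])
    verdicts = [evaluate_hairpin(w.sequence, w.mature_span, thresholds)
                for w in scan_windows(hit, genome.scaffolds, thresholds)]
    assert any(v.passes for v in verdicts)
    best = min((v for v in verdicts if v.passes), key=lambda v: v.mfe)
    assert best.n_loops == 1
    assert best.paired_frac >= 0.5
    assert best.mismatches_in_mature <= 4
    assert best.mfe < best.mfe_threshold


def test_verdict_reasons_consistency(thresholds):
    # an unstructured window fails with explicit reasons ({A,C} cannot
    # form any base pair)
    v = evaluate_hairpin("AACC" * 25, (10, 31), thresholds)
    assert not v.passes
    assert v.reasons
    assert v.mfe_threshold == pytest.approx(thresholds.mfe_coeff * 100)


def test_mature_span_validation(thresholds):
    with pytest.raises(ValueError):
        evaluate_hairpin("ACGT" * 10, (30, 60), thresholds)


# --- context ---------------------------------------------------------------

GENES = [GeneModel("g1", "g1.t1", "s", "+", [(100, 200), (400, 500)])]


def test_classify_exon():
    assert classify_context(("s", 150, 170), GENES) == "exon"


def test_classify_intron():
    assert classify_context(("s", 250, 270), GENES) == "intron"


def test_classify_intergenic():
    assert classify_context(("s", 900, 920), GENES) == "intergenic"
    assert classify_context(("other", 150, 170), GENES) == "intergenic"


def test_classify_one_nt_exon_overlap():
    assert classify_context(("s", 199, 220), GENES) == "exon"
    assert classify_context(("s", 200, 220), GENES) == "intron"


# --- suffix/prefix overlap -------------------------------------------------

def test_published_pair_overlap():
    mir03 = "CGGGAGGGGGAGGGAAGGCT"
    mir04 = "GGAAGGCTGAGTGCTGCATGT"
    assert suffix_prefix_overlap(mir03, mir04) == 8


def test_self_overlap_is_length():
    assert suffix_prefix_overlap("ACGT", "ACGT") == 4


def test_disjoint_alphabets():
    assert suffix_prefix_overlap("AAAA", "CCCC") == 0


# --- summaries over the bundled reference set ------------------------------

@pytest.fixture(scope="module")
def reference_summary():
    return summarize_candidates(reference_candidates())


def test_reference_lengths(reference_summary):
    assert reference_summary["median_length"] == 21
    assert reference_summary["min_length"] == 18
    assert reference_summary["max_length"] == 24


def test_reference_abundance(reference_summary):
    assert reference_summary["min_abundance"] == 3
    assert reference_summary["max_abundance"] == 1459
    assert reference_summary["n_with_star"] == 4


def test_reference_precursors(reference_summary):
    assert reference_summary["max_precursor_length"] == 252
    assert reference_summary["median_precursor_length"] == 93


def test_reference_context(reference_summary):
    assert reference_summary["context_percent"] == {"intergenic": 78,
                                                    "intron": 22}


def test_summarize_empty_rejected():
    with pytest.raises(ValueError):
        summarize_candidates([])


def test_summarize_lower_median_convention():
    cands = [MiRNACandidate(id=str(k), sequence="A" * n, length=n,
                            abundance=1, star_abundance=None,
                            precursor_length=80, genomic_region="intergenic")
             for k, n in enumerate([20, 21, 22, 23])]
    assert summarize_candidates(cands)["median_length"] == 21  # lower median


# --- full pipeline on a small genome ---------------------------------------

@pytest.fixture(scope="module")
def small_world(thresholds):
    genome = build_genome(1, 6000, 0.6, seed=17)
    with_star = plant_feature(genome, "mirna_hairpin",
                              {"mature_count": 50, "star_count": 2},
                              seed=1, thresholds=thresholds)
    no_star_low = plant_feature(genome, "mirna_hairpin",
                                {"mature_count": 50, "star_count": 0},
                                seed=2, thresholds=thresholds)
    no_star_high = plant_feature(genome, "mirna_hairpin",
                                 {"mature_count": 150, "star_count": 0},
                                 seed=3, thresholds=thresholds)
    lib = simulate_reads(genome, depth=100, noise_frac=0.0, seed=5)
    reads = [UniqueRead(r.sequence, r.count) for r in lib.records]
    return genome, (with_star, no_star_low, no_star_high), reads


def test_call_mirnas_empty_input(thresholds):
    genome = {"s": "ACGT" * 1000}
    assert call_mirnas([], genome, [], thresholds) == []


def test_abundance_rules(small_world, thresholds):
    genome, (with_star, no_star_low, no_star_high), reads = small_world
    cands = call_mirnas(reads, genome.scaffolds, genome.genes, thresholds)
    seqs = {c.sequence for c in cands}
    assert with_star.payload["mature_seq"] in seqs  # 50 >= 3 with star
    assert no_star_low.payload["mature_seq"] not in seqs  # 50 < 100, no star
    assert no_star_high.payload["mature_seq"] in seqs  # 150 >= 100


def test_threshold_monotonicity(small_world):
    genome, _, reads = small_world
    loose = call_mirnas(reads, genome.scaffolds, genome.genes,
                        Thresholds(min_abund_no_star=100))
    tight = call_mirnas(reads, genome.scaffolds, genome.genes,
                        Thresholds(min_abund_no_star=1000))
    tighter_mfe = call_mirnas(reads, genome.scaffolds, genome.genes,
                              Thresholds(mfe_coeff=-0.6))
    assert len(tight) <= len(loose)
    assert len(tighter_mfe) <= len(loose)


def test_candidate_self_consistency(pipeline42, thresholds):
    # every reported candidate's precursor re-evaluates to passes=True
    for c in pipeline42.candidates:
        a = c.precursor_sequence.find(c.sequence)
        assert a >= 0
        verdict = evaluate_hairpin(c.precursor_sequence,
                                   (a, a + len(c.sequence)), thresholds)
        assert verdict.passes, (c.id, verdict.reasons)
        assert c.id.startswith("cand")


def test_candidates_sorted_in_genome_order(pipeline42):
    cands = pipeline42.candidates
    keys = [(c.scaffold, c.start) for c in cands]
    assert keys == sorted(keys)
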