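"""Endogenous siRNA classification.

Four classes of non-miRNA small RNAs: repeat-associated (containment in
masked repeat intervals), phased trans-acting (exact hypergeometric
phasing statistic over fixed windows), natural-antisense (reads mapping
antisense to exons, plus overlapping opposite-strand gene pairs), and
piRNA-like (k-mer Fisher discriminant).  Positional base-composition
diagnostics (5'-U, position-10 A) are reported but never used as
filters.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np

from srnakit.config import Thresholds
from srnakit.genome_index import Hit
from srnakit.io_formats import GeneModel

#: antisense-strand phase register offset (Dicer 2-nt overhang geometry)
ANTISENSE_PHASE_OFFSET = 2


# ---------------------------------------------------------------------------
# ra-siRNA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatCallSummary:
    n_unique_repeat: int
    n_unique_total: int
    unique_fraction: float
    weighted_repeat: int
    weighted_total: int
    weighted_fraction: float


def rasirna_calls(hits_by_read: dict[str, list[Hit]],
                  repeats: list[tuple[str, int, int]],
                  counts: Optional[dict[str, int]] = None):
    """Flag repeat-associated reads: a hit counts iff fully contained in
    a masked interval (a read entirely inside a repeat is unambiguously
    repeat-derived; straddling hits are not flagged).

    Returns (flagged_hits, summary) where the summary reports both the
    unique-read and count-weighted fractions of repeat-associated reads.
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e in repeats:
        by_scaffold.setdefault(scaf, []).append((s, e))

    def contained(h: Hit) -> bool:
        return any(h.start >= s and h.end <= e
                   for s, e in by_scaffold.get(h.scaffold, ()))

    flagged: list[Hit] = []
    repeat_reads: set[str] = set()
    for read, hits in hits_by_read.items():
        for h in hits:
            if contained(h):
                flagged.append(h)
                repeat_reads.add(read)
    counts = counts or {}
    n_total = len(hits_by_read)
    w_total = sum(counts.get(r, 1) for r in hits_by_read)
    w_repeat = sum(counts.get(r, 1) for r in repeat_reads)
    summary = RepeatCallSummary(
        n_unique_repeat=len(repeat_reads), n_unique_total=n_total,
        unique_fraction=len(repeat_reads) / n_total if n_total else 0.0,
        weighted_repeat=w_repeat, weighted_total=w_total,
        weighted_fraction=w_repeat / w_total if w_total else 0.0)
    return flagged, summary


# ---------------------------------------------------------------------------
# ta-siRNA phasing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasedLocus:
    scaffold: str
    start: int  # window start
    register: int  # phase register in [0, phase_len)
    k: int  # occupied in-phase positions
    n: int  # occupied positions total
    K: int  # in-phase positions available
    N: int  # total positions available
    p_value: float


def phasing_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts in-phase positions among ``n`` occupied positions drawn
    without replacement from ``N`` available positions of which ``K``
    are in phase.  Computed with log-stable arithmetic (lgamma), summed
    exactly over the tail.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric counts "
                         f"k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return (math.lgamma(a + 1) - math.lgamma(b + 1)
                - math.lgamma(a - b + 1))

    denom = log_comb(N, n)
    total = 0.0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += math.exp(log_comb(K, x) + log_comb(N - K, n - x) - denom)
    return min(1.0, total)


def tasirna_scan(hits: list[Hit], thresholds: Thresholds,
                 count_both_strands_once: bool = False) -> list[PhasedLocus]:
    """Scan phase-length windows anchored at each distinct 21-nt read
    start and report significantly phased loci (p <= phase_alpha).

    Occupancy counts distinct (strand, start) positions in the window on
    both strands, the antisense register offset by +2 nt; with
    ``count_both_strands_once`` a position occupied on both strands
    counts once.  Hits must be pre-restricted to phase-length reads with
    repeat-derived hits excluded upstream.  Overlapping significant
    windows are deduplicated, keeping the lowest p-value.
    """
    plen, window = thresholds.phase_len, thresholds.phase_window
    for h in hits:
        if h.end - h.start != plen:
            raise ValueError("tasirna_scan requires phase-length hits only")
    by_scaffold: dict[str, set[tuple[int, str]]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold, set()).add((h.start, h.strand))

    n_regs = window // plen
    K = n_regs if count_both_strands_once else 2 * n_regs
    N = window if count_both_strands_once else 2 * window

    raw: list[PhasedLocus] = []
    for scaffold, positions in sorted(by_scaffold.items()):
        for anchor, anchor_strand in sorted(positions):
            start = anchor if anchor_strand == "+" else \
                anchor - ANTISENSE_PHASE_OFFSET
            occupied = {(p, s) for p, s in positions
                        if start <= p <= start + window - plen}
            if count_both_strands_once:
                occupied = {(p, "+") for p, _ in occupied}
            n = len(occupied)
            k = 0
            for p, s in occupied:
                off = (p - start) % plen
                if (s == "+" and off == 0) or \
                        (s == "-" and off == ANTISENSE_PHASE_OFFSET):
                    k += 1
            if n == 0 or k == 0:
                continue
            p_val = phasing_pvalue(k, n, K, N)
            if p_val <= thresholds.phase_alpha:
                raw.append(PhasedLocus(scaffold, start, start % plen,
                                       k, n, K, N, p_val))
    # deduplicate overlapping windows, best p first
    kept: list[PhasedLocus] = []
    for locus in sorted(raw, key=lambda r: (r.p_value, r.scaffold, r.start)):
        if not any(l.scaffold == locus.scaffold
                   and locus.start < l.start + window
                   and l.start < locus.start + window for l in kept):
            kept.append(locus)
    return sorted(kept, key=lambda r: (r.scaffold, r.start))


# ---------------------------------------------------------------------------
# nat-siRNA
# ---------------------------------------------------------------------------

def natsirna_calls(hits_by_read: dict[str, list[Hit]],
                   genes: list[GeneModel],
                   thresholds: Thresholds):
    """Antisense-exon hits plus overlapping opposite-strand gene pairs.

    A hit is flagged when its locus overlaps an exon of a gene on the
    OPPOSITE strand.  Gene pairs are reported when their spans overlap
    by at least ``nat_min_overlap`` on opposite strands.
    """
    flagged: list[Hit] = []
    for hits in hits_by_read.values():
        for h in hits:
            for g in genes:
                if g.scaffold != h.scaffold or g.strand == h.strand:
                    continue
                if any(h.start < xe and h.end > xs for xs, xe in g.exons):
                    flagged.append(h)
                    break
    pairs = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            if ga.scaffold != gb.scaffold or ga.strand == gb.strand:
                continue
            (s1, e1), (s2, e2) = ga.span, gb.span
            ov = min(e1, e2) - max(s1, s2)
            if ov >= thresholds.nat_min_overlap:
                pairs.append((ga.gene_id, gb.gene_id, ov))
    return flagged, pairs


_CONTEXT_LABELS = ("antisense_exon", "antisense_intron", "intergenic",
                   "sense_exon", "sense_intron")


def annotate_hit_context(hits_by_read: dict[str, list[Hit]],
                         genes: list[GeneModel]):
    """Per-read single context label with the most-frequent-feature rule.

    Each hit gets one of sense_exon / antisense_exon / sense_intron /
    antisense_intron / intergenic.  A read mapping to several features
    takes its most frequent non-intergenic label (ties broken to the
    lexicographically first label); reads with only intergenic hits are
    intergenic.  Returns (label per read, label -> read-count summary).
    """
    def hit_label(h: Hit) -> str:
        best = "intergenic"
        for g in genes:
            if g.scaffold != h.scaffold:
                continue
            gs, ge = g.span
            if not (h.start < ge and h.end > gs):
                continue
            rel = "sense" if g.strand == h.strand else "antisense"
            if any(h.start < xe and h.end > xs for xs, xe in g.exons):
                return f"{rel}_exon"
            best = f"{rel}_intron"
        return best

    labels: dict[str, str] = {}
    for read, hits in hits_by_read.items():
        tally = Counter(hit_label(h) for h in hits)
        non_inter = {lab: c for lab, c in tally.items() if lab != "intergenic"}
        if non_inter:
            top = max(non_inter.values())
            labels[read] = min(l for l, c in non_inter.items() if c == top)
        else:
            labels[read] = "intergenic"
    summary = Counter(labels.values())
    return labels, {lab: summary.get(lab, 0) for lab in _CONTEXT_LABELS}


# ---------------------------------------------------------------------------
# piRNA k-mer Fisher discriminant
# ---------------------------------------------------------------------------

_KMER_SIZES = (1, 2, 3, 4, 5)
#: 4 + 16 + 64 + 256 + 1024
FEATURE_DIM = sum(4 ** k for k in _KMER_SIZES)

_KMER_INDEX = {}
_offset = 0
for _k in _KMER_SIZES:
    for _i, _mer in enumerate(product("ACGT", repeat=_k)):
        _KMER_INDEX["".join(_mer)] = _offset + _i
    _offset += 4 ** _k


def kmer_features(seq: str) -> np.ndarray:
    """Normalized k-mer frequency vector, k = 1..5 (dimension 1364)."""
    seq = seq.upper().replace("U", "T")
    v = np.zeros(FEATURE_DIM)
    for k in _KMER_SIZES:
        n = len(seq) - k + 1
        if n <= 0:
            continue
        for i in range(n):
            idx = _KMER_INDEX.get(seq[i:i + k])
            if idx is not None:
                v[idx] += 1.0 / n
    return v


@dataclass
class PirnaModel:
    weights: np.ndarray
    threshold: float
    positive_above: bool = True

    def score(self, seq: str) -> float:
        return float(kmer_features(seq) @ self.weights)

    def classify(self, seq: str) -> bool:
        s = self.score(seq)
        return s > self.threshold if self.positive_above else s < self.threshold


def fit_pirna_model(train_pos, train_neg, ridge: float = 1e-3) -> PirnaModel:
    """Fisher linear discriminant on k-mer features.

    Pooled within-class covariance with a ridge term (the feature space
    is far larger than typical training sets, so the raw covariance is
    always singular); threshold at the midpoint of the projected class
    means.  Deterministic.
    """
    if not train_pos or not train_neg:
        raise ValueError("both training sets must be non-empty")
    xp = np.array([kmer_features(s) for s in _seqs(train_pos)])
    xn = np.array([kmer_features(s) for s in _seqs(train_neg)])
    mp, mn = xp.mean(axis=0), xn.mean(axis=0)

    def scatter(x, m):
        d = x - m
        return d.T @ d

    sw = scatter(xp, mp) + scatter(xn, mn) + ridge * np.eye(FEATURE_DIM)
    w = np.linalg.solve(sw, mp - mn)
    proj_p, proj_n = float(mp @ w), float(mn @ w)
    return PirnaModel(weights=w, threshold=(proj_p + proj_n) / 2.0,
                      positive_above=proj_p > proj_n)


def _seqs(records):
    return [r.sequence if hasattr(r, "sequence") else str(r) for r in records]


def pirna_classify(train_pos, train_neg, queries,
                   thresholds: Thresholds | None = None):
    """Train on labelled sets and score queries (26-30 nt).

    Returns a list of (sequence, score, is_pirna_like).
    """
    thr = thresholds or Thresholds()
    model = fit_pirna_model(train_pos, train_neg)
    out = []
    for seq in _seqs(queries):
        if not (thr.pirna_len_min <= len(seq) <= thr.pirna_len_max):
            raise ValueError(f"query length {len(seq)} outside piRNA window")
        out.append((seq, model.score(seq), model.classify(seq)))
    return out


# ---------------------------------------------------------------------------
# positional bias diagnostics
# ---------------------------------------------------------------------------

def positional_bias(seqs, position: int, base: str) -> float:
    """Fraction of sequences (length >= position) carrying ``base`` at the
    1-based ``position``; 0.0 with a warning for an empty set."""
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    base = base.upper().replace("U", "T")
    eligible = [s for s in _seqs(seqs) if len(s) >= position]
    if not eligible:
        import warnings

        warnings.warn("positional_bias over an empty sequence set")
        return 0.0
    hits = sum(1 for s in eligible
               if s[position - 1].upper().replace("U", "T") == base)
    return hits / len(eligible)


def simulate_pirna_like(n: int, seed: int, length_range=(26, 30),
                        u5_bias: float = 0.8) -> list[str]:
    """Synthetic piRNA-like training sequences: 5'-U biased with a
    skewed (repeat-like) base composition."""
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        ln = rng.randint(*length_range)
        s = ["T" if rng.random() < u5_bias else rng.choice("ACG")]
        for _k in range(ln - 1):
            s.append(rng.choices("ACGT", weights=[0.4, 0.1, 0.1, 0.4])[0])
        out.append("".join(s))
    return out


def simulate_background(n: int, seed: int, length_range=(26, 30),
                        gc: float = 0.6) -> list[str]:
    """Uniform GC-biased background sequences for classifier training."""
    rng = random.Random(seed)
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return ["".join(rng.choices("ACGT", weights=w,
                                k=rng.randint(*length_range)))
            for _ in range(n)]
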