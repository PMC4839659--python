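"""miRNA candidate discovery: window scan, hairpin curation, star duplex
detection, abundance screening, and genomic-context classification.

The curation rules: a candidate precursor must fold into a single-loop
hairpin with at least half its bases paired, at most four mismatches and
two short bulges in the mature region, and an MFE below a per-length
threshold (coefficient x precursor length).  A candidate needs library
abundance >= 3 together with a star read on the opposite arm (2-nt
3'-overhang duplex geometry), or abundance >= 100 on hairpin evidence
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from srnakit.config import Thresholds
from srnakit.genome_index import GenomeIndex, Hit, build_index, map_library
from srnakit.io_formats import GeneModel
from srnakit.read_processing import UniqueRead, revcomp
from srnakit import rna_fold
from srnakit.rna_fold import FoldResult

#: flank kept between the mature read and the window edge for the
#: 5'- and 3'-anchored placements
ANCHOR_FLANK = 10
#: tolerance (nt, each end) when matching a mapped read to the expected
#: star span, absorbing Dicer-cleavage wobble
STAR_SPAN_TOLERANCE = 1


@dataclass(frozen=True)
class Window:
    """A candidate precursor window on one genome strand.

    ``sequence`` reads 5'->3' on the hit's strand; ``mature_span`` is the
    mature read's 0-based half-open interval in window coordinates.
    """

    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_span: tuple[int, int]

    def to_window_coords(self, gstart: int, gend: int) -> tuple[int, int]:
        """Convert a genome interval inside this window to window coords."""
        if self.strand == "+":
            return gstart - self.start, gend - self.start
        return self.end - gend, self.end - gstart


@dataclass(frozen=True)
class HairpinVerdict:
    passes: bool
    reasons: tuple[str, ...]
    paired_frac: float
    n_loops: int
    mismatches_in_mature: int
    bulges_in_mature: int
    mfe: float
    mfe_threshold: float
    fold: Optional[FoldResult] = None


@dataclass
class MiRNACandidate:
    id: str
    sequence: str
    length: int
    abundance: int
    star_abundance: Optional[int]
    precursor_length: int
    genomic_region: str
    scaffold: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    precursor_sequence: str = ""
    structure: str = ""
    mfe: float = 0.0
    n_loci: int = 1

    @property
    def has_star(self) -> bool:
        return self.star_abundance is not None


def scan_windows(hit: Hit, genome: dict[str, str],
                 thresholds: Thresholds) -> list[Window]:
    """Candidate precursor windows around one exact hit.

    For each window length (window_min..window_max in window_step
    increments) up to three placements are emitted: mature anchored near
    the window 5' end, near the 3' end (both with a 10-nt flank), and
    centered.  Placements are shifted to stay inside the scaffold and
    deduplicated; windows that cannot contain the mature read are
    dropped.  Window sequence is taken on the hit's strand.
    """
    scaffold_seq = genome[hit.scaffold]
    slen = len(scaffold_seq)
    read_len = hit.end - hit.start
    windows: list[Window] = []
    seen: set[tuple[int, int]] = set()
    for w in range(thresholds.window_min, thresholds.window_max + 1,
                   thresholds.window_step):
        if w < read_len or w > slen:
            continue
        if hit.strand == "+":
            starts = [hit.start - ANCHOR_FLANK,
                      hit.end + ANCHOR_FLANK - w,
                      hit.start - (w - read_len) // 2]
        else:
            starts = [hit.end + ANCHOR_FLANK - w,
                      hit.start - ANCHOR_FLANK,
                      hit.start - (w - read_len) // 2]
        for ws in starts:
            ws = max(0, min(ws, slen - w))
            we = ws + w
            if hit.start < ws or hit.end > we or (ws, we) in seen:
                continue
            seen.add((ws, we))
            seq = scaffold_seq[ws:we]
            if hit.strand == "-":
                seq = revcomp(seq)
            win = Window(hit.scaffold, ws, we, hit.strand, seq, (0, 0))
            span = win.to_window_coords(hit.start, hit.end)
            windows.append(replace(win, mature_span=span))
    return windows


def mfe_screen(mfe: float, precursor_length: int,
               thresholds: Thresholds) -> bool:
    """Energy screen: MFE must be strictly below coeff x length."""
    return mfe < thresholds.mfe_coeff * precursor_length


def _count_hairpin_loops(pairs) -> int:
    """Number of terminal loops = pairs with nothing paired inside."""
    loops = 0
    pairset = sorted(pairs)
    for i, j in pairset:
        if not any(i < p < j for p, _ in pairset) and \
           not any(i < q < j for _, q in pairset):
            loops += 1
    return loops


def evaluate_hairpin(window_seq: str, mature_span: tuple[int, int],
                     thresholds: Thresholds) -> HairpinVerdict:
    """Fold a window and test it against the hairpin curation criteria.

    Criterion codes on failure: ``multi_loop`` (more than one terminal
    loop, or none), ``low_paired_frac``, ``mismatch_excess``,
    ``bulge_excess``, ``bulge_too_long``, ``mature_unpaired``,
    ``mature_spans_loop``, ``mfe_above_threshold``.
    """
    a, b = mature_span
    if not (0 <= a < b <= len(window_seq)):
        raise ValueError(f"mature span {mature_span} outside window")
    fold = rna_fold.fold_mfe(window_seq)
    pm = fold.pair_map()
    n = len(window_seq)
    reasons: list[str] = []

    n_loops = _count_hairpin_loops(fold.pairs)
    if n_loops != 1:
        reasons.append("multi_loop")
    paired_frac = sum(1 for p in pm if p >= 0) / n
    if paired_frac < thresholds.min_paired_frac:
        reasons.append("low_paired_frac")

    mismatches, bulges = _mature_defects(pm, a, b, thresholds, reasons)
    if mismatches > thresholds.max_mismatch_mature:
        reasons.append("mismatch_excess")
    if bulges > thresholds.max_bulge_mature:
        reasons.append("bulge_excess")

    mfe_threshold = thresholds.mfe_coeff * n
    if not mfe_screen(fold.energy, n, thresholds):
        reasons.append("mfe_above_threshold")

    return HairpinVerdict(
        passes=not reasons, reasons=tuple(reasons), paired_frac=paired_frac,
        n_loops=n_loops, mismatches_in_mature=mismatches,
        bulges_in_mature=bulges, mfe=fold.energy,
        mfe_threshold=mfe_threshold, fold=fold)


def _mature_defects(pm, a: int, b: int, thresholds: Thresholds,
                    reasons: list[str]) -> tuple[int, int]:
    """Mismatch and bulge counts in the mature region.

    An unpaired mature position facing a nucleotide on the opposing arm
    is a mismatch; a maximal run of unpaired mature positions with no
    opposing nucleotide is a bulge (each run limited to max_bulge_len).
    """
    paired = [p for p in range(a, b) if pm[p] >= 0]
    if not paired:
        reasons.append("mature_unpaired")
        return b - a, 0
    partners = [pm[p] for p in paired]
    # in any single stem, partner indices strictly descend; the mature
    # must also sit entirely on one arm (all partners on one side)
    descending = all(x > y for x, y in zip(partners, partners[1:]))
    one_arm = (all(pm[p] > p for p in paired)
               or all(pm[p] < p for p in paired))
    if not (descending and one_arm):
        reasons.append("mature_spans_loop")
        return b - a, 0
    mismatches = (paired[0] - a) + (b - 1 - paired[-1])
    bulges = 0
    for p, q in zip(paired, paired[1:]):
        gap_m = q - p - 1
        gap_o = abs(pm[p] - pm[q]) - 1
        mismatches += min(gap_m, gap_o)
        if gap_m > gap_o:
            bulges += 1
            if gap_m - gap_o > thresholds.max_bulge_len:
                if "bulge_too_long" not in reasons:
                    reasons.append("bulge_too_long")
    return mismatches, bulges


def expected_star_span(fold: FoldResult, mature_span: tuple[int, int],
                       overhang: int = 2) -> Optional[tuple[int, int]]:
    """Window-coordinate span of the star sequence implied by the fold.

    Assumes the canonical duplex geometry: the mature and star pair
    across the loop with an ``overhang``-nt 3' overhang on both strands.
    Returns None when the mature arm cannot be resolved.
    """
    a, b = mature_span
    pm = fold.pair_map()
    n = len(pm)

    paired = [p for p in range(a, b) if pm[p] >= 0]
    if len(paired) < 2:
        return None
    partners = [pm[p] for p in paired]
    # one stem arm: partners strictly descending and all on one side
    if not all(x > y for x, y in zip(partners, partners[1:])):
        return None
    if not (all(pm[p] > p for p in paired) or all(pm[p] < p for p in paired)):
        return None

    def est_partner(p: int) -> int:
        # nearest paired mature position, extrapolated at stem slope -1
        q = min(paired, key=lambda q: abs(q - p))
        return pm[q] - (p - q)

    # duplex core pairs mature[a .. b-1-overhang] with star[s .. e-1-overhang]
    # (both strands carry an `overhang`-nt 3' overhang), so the star span
    # is the same formula whichever arm the mature sits on
    span = (est_partner(b - 1 - overhang), est_partner(a) + overhang + 1)
    if span[0] < 0 or span[1] > n or span[0] >= span[1]:
        return None
    return span


def locate_star(fold: FoldResult, mature_span: tuple[int, int],
                window_reads, thresholds: Thresholds):
    """Find a mapped read occupying the expected star span.

    ``window_reads`` is an iterable of ``(start, end, count)`` spans in
    window coordinates for reads mapped inside the window on the same
    strand.  A star is reported only when a read coincides with the
    expected span within +/-1 nt at each end and the implied duplex has
    at most ``max_mismatch_mature`` mismatches.  Returns
    ``(star_span, star_count)`` or ``(None, None)``.
    """
    span = expected_star_span(fold, mature_span, thresholds.overhang)
    if span is None:
        return None, None
    a, b = mature_span
    pm = fold.pair_map()
    paired = [p for p in range(a, b) if pm[p] >= 0]
    if not paired:
        return None, None
    # duplex mismatches: mature positions (excluding the 3' overhang on
    # the 5' arm / the 5' offset on the 3' arm) left unpaired by the fold
    if pm[paired[0]] > paired[0]:  # mature on 5' arm
        core = range(a, b - thresholds.overhang)
    else:
        core = range(a + thresholds.overhang, b)
    mismatches = sum(1 for p in core if pm[p] < 0)
    if mismatches > thresholds.max_mismatch_mature:
        return None, None
    best = None
    for rs, re_, count in window_reads:
        if (abs(rs - span[0]) <= STAR_SPAN_TOLERANCE
                and abs(re_ - span[1]) <= STAR_SPAN_TOLERANCE
                and not (rs == a and re_ == b)):
            if best is None or count > best[1]:
                best = ((rs, re_), count)
    return best if best else (None, None)


def classify_context(locus: tuple[str, int, int],
                     genes: list[GeneModel]) -> str:
    """Label a locus exon / intron / intergenic (strand-agnostic).

    Exon wins on any >= 1 nt exon overlap; otherwise a locus inside a
    gene span is intronic; otherwise intergenic.
    """
    scaffold, start, end = locus
    in_gene = False
    for g in genes:
        if g.scaffold != scaffold:
            continue
        gs, ge = g.span
        if start < ge and end > gs:
            in_gene = True
            for xs, xe in g.exons:
                if start < xe and end > xs:
                    return "exon"
    return "intron" if in_gene else "intergenic"


def suffix_prefix_overlap(a: str, b: str) -> int:
    """Length of the longest suffix of ``a`` equal to a prefix of ``b``."""
    for k in range(min(len(a), len(b)), 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def call_mirnas(reads, genome: dict[str, str], genes: list[GeneModel],
                thresholds: Thresholds,
                index: GenomeIndex | None = None) -> list[MiRNACandidate]:
    """Run the full discovery pipeline on a collapsed, filtered library.

    ``reads`` must already be length-filtered to the miRNA window and
    contaminant-filtered.  Pipeline per read: exact mapping -> window
    scan -> hairpin curation -> star detection -> abundance rules ->
    overlap deduplication -> context classification.  Candidates are
    numbered in genome order.
    """
    if index is None:
        index = build_index(genome)
    reads = [r for r in reads
             if thresholds.mirna_len_min <= len(r.sequence)
             <= thresholds.mirna_len_max]
    hits_by_read, _hyper = map_library(index, reads)
    counts = {r.sequence: r.count for r in reads}

    # per-scaffold/strand hit lists for star lookup
    by_loc: dict[tuple[str, str], list[Hit]] = {}
    for hits in hits_by_read.values():
        for h in hits:
            by_loc.setdefault((h.scaffold, h.strand), []).append(h)

    prelim: list[MiRNACandidate] = []
    for seq, hits in sorted(hits_by_read.items()):
        count = counts[seq]
        if count < thresholds.min_abund_with_star:
            continue
        best: tuple[tuple[float, int, int], Window, HairpinVerdict] | None = None
        for hit in hits:
            for win in scan_windows(hit, genome, thresholds):
                verdict = evaluate_hairpin(win.sequence, win.mature_span,
                                           thresholds)
                if not verdict.passes:
                    continue
                key = (verdict.mfe, win.end - win.start, win.start)
                if best is None or key < best[0]:
                    best = (key, win, verdict)
        if best is None:
            continue
        _, win, verdict = best
        window_reads = [
            (*win.to_window_coords(h.start, h.end), counts[h.read])
            for h in by_loc.get((win.scaffold, win.strand), [])
            if h.start >= win.start and h.end <= win.end]
        _span, star_count = locate_star(verdict.fold, win.mature_span,
                                        window_reads, thresholds)
        if star_count is None and count < thresholds.min_abund_no_star:
            continue
        prelim.append(MiRNACandidate(
            id="", sequence=seq, length=len(seq), abundance=count,
            star_abundance=star_count,
            precursor_length=win.end - win.start,
            genomic_region=classify_context(
                (win.scaffold, win.start, win.end), genes),
            scaffold=win.scaffold, start=win.start, end=win.end,
            strand=win.strand, precursor_sequence=win.sequence,
            structure=verdict.fold.structure, mfe=verdict.mfe,
            n_loci=len(hits)))

    deduped = _dedupe(prelim)
    deduped.sort(key=lambda c: (c.scaffold, c.start, c.sequence))
    for k, cand in enumerate(deduped, start=1):
        cand.id = f"cand{k:02d}"
    return deduped


def _dedupe(cands: list[MiRNACandidate]) -> list[MiRNACandidate]:
    """Merge candidates whose precursor loci overlap >= 50%.

    The higher-abundance mature wins.  Precursors on different scaffolds
    are never merged.
    """
    kept: list[MiRNACandidate] = []
    for cand in sorted(cands, key=lambda c: -c.abundance):
        merged = False
        for other in kept:
            if cand.scaffold != other.scaffold or cand.strand != other.strand:
                continue
            ov = min(cand.end, other.end) - max(cand.start, other.start)
            if ov <= 0:
                continue
            if (ov >= 0.5 * (cand.end - cand.start)
                    or ov >= 0.5 * (other.end - other.start)):
                merged = True
                break
        if not merged:
            kept.append(cand)
    return kept


def summarize_candidates(cands) -> dict:
    """Summary statistics over a candidate table.

    The median is the lower median for even n; context percentages are
    rounded to the nearest integer.
    """
    cands = list(cands)
    if not cands:
        raise ValueError("cannot summarize an empty candidate list")

    def lower_median(vals):
        vals = sorted(vals)
        return vals[(len(vals) - 1) // 2]

    lengths = [c.length for c in cands]
    abunds = [c.abundance for c in cands if c.abundance is not None]
    precs = [c.precursor_length for c in cands]
    n = len(cands)
    contexts = {}
    for c in cands:
        label = c.genomic_region.lower()
        contexts[label] = contexts.get(label, 0) + 1
    return {
        "n_candidates": n,
        "median_length": lower_median(lengths),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "min_abundance": min(abunds) if abunds else None,
        "max_abundance": max(abunds) if abunds else None,
        "n_with_star": sum(1 for c in cands if c.star_abundance is not None),
        "median_precursor_length": lower_median(precs),
        "min_precursor_length": min(precs),
        "max_precursor_length": max(precs),
        "context_percent": {k: round(100.0 * v / n)
                            for k, v in sorted(contexts.items())},
    }


# ---------------------------------------------------------------------------
# bundled reference candidate set (regression fixture)
# ---------------------------------------------------------------------------

#: Published 18-candidate reference set used as a regression fixture:
#: (id, mature sequence, abundance or None, star abundance or None,
#:  precursor length, genomic region)
_REFERENCE_ROWS = [
    ("mir01", "TGGAGTGGAGTGGAGTGGAGTGG", None, None, 82, "Intergenic"),
    ("mir02", "CGTCCTAATCCTTGGCCTG", 3, 10, 170, "intron"),
    ("mir03", "CGGGAGGGGGAGGGAAGGCT", 141, None, 193, "Intergenic"),
    ("mir04", "GGAAGGCTGAGTGCTGCATGT", 1459, None, 252, "intron"),
    ("mir05", "CGGCTGGCTGCGCGGGGACTACG", 317, 190, 79, "Intergenic"),
    ("mir06", "CAGAAACTCACGGACCTCGAC", 27, None, 76, "Intergenic"),
    ("mir07", "AGTGGATAGCGTGTTGGG", 10, None, 82, "Intergenic"),
    ("mir08", "CAACCATGTGGCGTCGGCACA", 11, None, 114, "Intergenic"),
    ("mir09", "GCGGCCCTCGAACGGACACCGG", 10, None, 80, "Intron"),
    ("mir10", "CGGAGGAGATGTGCCGTTCCG", 120, None, 144, "Intergenic"),
    ("mir11", "CATGTAGGTCGCGAACGGGTT", 8, None, 119, "Intergenic"),
    ("mir12", "GTCAGTGAGGACGCTGTATCAAGG", 12, None, 94, "Intergenic"),
    ("mir13", "GCGTCAGTCGACCGTGGCACATCC", 7, 1, 93, "Intron"),
    ("mir14", "CGAGGTGTCCGAAGATGTATG", 15, None, 89, "Intergenic"),
    ("mir15", "GTGGCTAGTATCCGACGCTGTC", 11, None, 127, "Intergenic"),
    ("mir16", "AAGAAGGCCGTGGCGCAACTG", 75, 1, 92, "Intergenic"),
    ("mir17", "CGGGGCTGCCGATTCATCGGT", 54, None, 85, "Intergenic"),
    ("mir18", "CGTTGATGAGGCCGATCTGGT", 21, None, 95, "Intergenic"),
]


def reference_candidates() -> list[MiRNACandidate]:
    """The bundled reference candidate set as candidate records."""
    return [MiRNACandidate(id=i, sequence=s, length=len(s), abundance=a,
                           star_abundance=st, precursor_length=pl,
                           genomic_region=reg)
            for i, s, a, st, pl, reg in _REFERENCE_ROWS]
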