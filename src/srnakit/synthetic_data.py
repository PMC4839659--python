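"""Truth-labelled synthetic genomes and read libraries.

Every downstream stage of the pipeline can be exercised offline against
data with known ground truth: a GC-rich multi-scaffold genome carrying
planted miRNA hairpins (built by construction-then-verification against
the package's own hairpin evaluator), 21-nt phased loci, repeat-family
copies, overlapping antisense gene pairs, contaminant (tRNA/rRNA-like)
genes, and background gene models; plus a heavy-tailed read simulator.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from srnakit.config import Thresholds
from srnakit.genome_index import Hit
from srnakit.io_formats import GeneModel, SeqRecord
from srnakit.mirna_discovery import (evaluate_hairpin, expected_star_span,
                                     scan_windows)
from srnakit.read_processing import revcomp


class GenerationError(RuntimeError):
    """Raised when a feature cannot be constructed within the retry budget."""


#: minimum clearance between planted features (and to scaffold edges);
#: larger than window_max so precursor windows never mix features
FEATURE_MARGIN = 400

#: Dicer geometry: antisense-strand phase register is offset +2 nt
ANTISENSE_PHASE_OFFSET = 2

_PLACEMENT_RETRIES = 200
_HAIRPIN_RETRIES = 60


@dataclass
class PlantedFeature:
    kind: str
    scaffold: str
    start: int
    end: int  # half-open
    strand: str
    payload: dict = field(default_factory=dict)


@dataclass
class SyntheticGenome:
    scaffolds: dict[str, str]
    gc_content: float
    truth: list[PlantedFeature] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def gc_observed(self, name: str) -> float:
        seq = self.scaffolds[name]
        return (seq.count("G") + seq.count("C")) / len(seq)


def build_genome(n_scaffolds: int, scaffold_len: int, gc: float,
                 seed: int) -> SyntheticGenome:
    """Random genome with the requested GC content; seed-deterministic."""
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    if scaffold_len < 1000:
        raise ValueError("scaffold_len must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = random.Random(seed)
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    scaffolds = {
        f"scaffold_{k + 1}": "".join(
            rng.choices("ACGT", weights=weights, k=scaffold_len))
        for k in range(n_scaffolds)}
    return SyntheticGenome(scaffolds=scaffolds, gc_content=gc)


# ---------------------------------------------------------------------------
# feature planting
# ---------------------------------------------------------------------------

def _occupied(genome: SyntheticGenome, scaffold: str):
    for f in genome.truth:
        if f.scaffold == scaffold:
            yield (f.start, f.end)
    for g in genome.genes:
        if g.scaffold == scaffold:
            yield g.span


def _place(genome: SyntheticGenome, length: int, rng: random.Random,
           scaffold: Optional[str] = None,
           pos: Optional[int] = None) -> tuple[str, int]:
    """Find a collision-free locus with FEATURE_MARGIN clearance."""
    names = [scaffold] if scaffold else list(genome.scaffolds)
    for _ in range(_PLACEMENT_RETRIES):
        name = rng.choice(names)
        slen = len(genome.scaffolds[name])
        if slen < length + 2 * FEATURE_MARGIN:
            continue
        p = pos if pos is not None else rng.randrange(
            FEATURE_MARGIN, slen - length - FEATURE_MARGIN)
        clear = all(p + length + FEATURE_MARGIN <= s
                    or p >= e + FEATURE_MARGIN
                    for s, e in _occupied(genome, name))
        if clear:
            return name, p
        if pos is not None:
            raise GenerationError(f"requested locus {name}:{pos} collides "
                                  f"with an existing feature")
    raise GenerationError("no collision-free locus found")


def _overwrite(genome: SyntheticGenome, scaffold: str, pos: int,
               seq: str) -> None:
    s = genome.scaffolds[scaffold]
    if pos < 0 or pos + len(seq) > len(s):
        raise GenerationError("feature does not fit in scaffold")
    genome.scaffolds[scaffold] = s[:pos] + seq + s[pos + len(seq):]


def _random_seq(rng: random.Random, n: int, gc: float = 0.6) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))


def _mutate(rng: random.Random, seq: str, n_sub: int) -> str:
    out = list(seq)
    for p in rng.sample(range(len(seq)), min(n_sub, len(seq))):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def plant_feature(genome: SyntheticGenome, kind: str, spec: dict,
                  seed: int,
                  thresholds: Thresholds | None = None) -> PlantedFeature:
    """Plant one feature; the genome sequence is overwritten at the locus.

    Supported kinds: mirna_hairpin, phased_locus, repeat_copy,
    antisense_pair, contaminant_gene, background_gene.  The truth record
    is appended to ``genome.truth`` (gene-like kinds also extend
    ``genome.genes``).
    """
    thresholds = thresholds or Thresholds()
    rng = random.Random(seed)
    planters = {
        "mirna_hairpin": _plant_hairpin,
        "phased_locus": _plant_phased,
        "repeat_copy": _plant_repeat,
        "antisense_pair": _plant_antisense_pair,
        "contaminant_gene": _plant_contaminant,
        "background_gene": _plant_background_gene,
    }
    if kind not in planters:
        raise ValueError(f"unknown feature kind {kind!r}")
    feature = planters[kind](genome, spec, rng, thresholds)
    genome.truth.append(feature)
    return feature


def _plant_hairpin(genome: SyntheticGenome, spec: dict, rng: random.Random,
                   thr: Thresholds) -> PlantedFeature:
    """Construct mature + loop + (mutated) reverse complement, then verify
    the locus against the real window scan / hairpin evaluator; redraw on
    failure."""
    mature_given = spec.get("mature")
    if mature_given is not None and not (
            thr.mirna_len_min <= len(mature_given) <= thr.mirna_len_max):
        raise GenerationError("requested mature length outside miRNA window")
    for _ in range(_HAIRPIN_RETRIES):
        mature = (mature_given.upper().replace("U", "T") if mature_given
                  else _random_seq(rng, rng.randint(20, 22)))
        loop = _random_seq(rng, rng.randint(8, 15), gc=0.4)
        star_arm = _mutate(rng, revcomp(mature),
                           spec.get("star_mismatches", 1))
        precursor = mature + loop + star_arm
        scaffold, pos = _place(genome, len(precursor), rng,
                               spec.get("scaffold"), spec.get("pos"))
        saved = genome.scaffolds[scaffold]
        _overwrite(genome, scaffold, pos, precursor)
        hit = Hit(scaffold, pos, pos + len(mature), "+", mature)
        best = None
        for win in scan_windows(hit, genome.scaffolds, thr):
            verdict = evaluate_hairpin(win.sequence, win.mature_span, thr)
            if verdict.passes:
                key = (verdict.mfe, win.end - win.start, win.start)
                if best is None or key < best[0]:
                    best = (key, win, verdict)
        star_seq = None
        star_interval = None
        if best is not None:
            _, win, verdict = best
            span = expected_star_span(verdict.fold, win.mature_span,
                                      thr.overhang)
            if span is not None:
                star_seq = win.sequence[span[0]:span[1]]
                star_interval = (win.start + span[0], win.start + span[1])
        if star_seq is None:
            genome.scaffolds[scaffold] = saved  # roll back and redraw
            continue
        # the truth interval covers the precursor and the star read (the
        # star's 3' overhang may protrude a little into the flank)
        return PlantedFeature(
            kind="mirna_hairpin", scaffold=scaffold,
            start=min(pos, star_interval[0]),
            end=max(pos + len(precursor), star_interval[1]), strand="+",
            payload={
                "mature_seq": mature,
                "star_seq": star_seq,
                "mature_count": spec.get("mature_count"),
                "star_count": spec.get("star_count"),
                "precursor": precursor,
            })
    raise GenerationError("could not construct a compliant hairpin "
                          f"in {_HAIRPIN_RETRIES} attempts")


def _plant_phased(genome: SyntheticGenome, spec: dict, rng: random.Random,
                  thr: Thresholds) -> PlantedFeature:
    """21-nt reads at register positions p + 21k (+ strand) and
    p + 21k + 2 (- strand) within one phase window."""
    n_sense = spec.get("n_phased", 9)
    n_anti = spec.get("n_phased_antisense", 0)
    n_off = spec.get("n_off_register", 0)
    window = thr.phase_window
    plen = thr.phase_len
    n_regs = window // plen
    if n_sense > n_regs or n_anti > n_regs:
        raise GenerationError("more phased positions requested than registers")
    scaffold, pos = _place(genome, window, rng, spec.get("scaffold"),
                           spec.get("pos"))
    reads = []
    for k in sorted(rng.sample(range(n_regs), n_sense)):
        p = pos + k * plen
        reads.append((genome.scaffolds[scaffold][p:p + plen], "+", p))
    for k in sorted(rng.sample(range(n_regs), n_anti)):
        p = pos + k * plen + ANTISENSE_PHASE_OFFSET
        reads.append((revcomp(genome.scaffolds[scaffold][p:p + plen]), "-", p))
    for _ in range(n_off):
        # off-register start: anything not congruent to the register
        while True:
            off = rng.randrange(window - plen)
            if off % plen not in (0, ANTISENSE_PHASE_OFFSET):
                break
        p = pos + off
        reads.append((genome.scaffolds[scaffold][p:p + plen], "+", p))
    return PlantedFeature(
        kind="phased_locus", scaffold=scaffold, start=pos, end=pos + window,
        strand="+",
        payload={"reads": reads, "n_phased": n_sense + n_anti,
                 "register": pos % plen})


def _plant_repeat(genome: SyntheticGenome, spec: dict, rng: random.Random,
                  thr: Thresholds) -> PlantedFeature:
    consensus = spec.get("consensus") or _random_seq(rng, spec.get("length", 400))
    scaffold, pos = _place(genome, len(consensus), rng, spec.get("scaffold"),
                           spec.get("pos"))
    _overwrite(genome, scaffold, pos, consensus)
    return PlantedFeature(
        kind="repeat_copy", scaffold=scaffold, start=pos,
        end=pos + len(consensus), strand="+",
        payload={"family": spec.get("family", "rf1"), "consensus": consensus})


def _plant_antisense_pair(genome: SyntheticGenome, spec: dict,
                          rng: random.Random,
                          thr: Thresholds) -> PlantedFeature:
    overlap = spec.get("overlap", 60)
    if overlap < thr.nat_min_overlap and not spec.get("allow_below_min", False):
        raise GenerationError(
            f"antisense overlap {overlap} below nat_min_overlap "
            f"({thr.nat_min_overlap}); pass allow_below_min to force")
    glen = spec.get("gene_length", 300)
    total = 2 * glen - overlap
    scaffold, pos = _place(genome, total, rng, spec.get("scaffold"),
                           spec.get("pos"))
    k = len(genome.genes)
    ga = GeneModel(f"natA{k}", f"natA{k}.t1", scaffold, "+",
                   [(pos, pos + glen)])
    gb = GeneModel(f"natB{k}", f"natB{k}.t1", scaffold, "-",
                   [(pos + glen - overlap, pos + total)])
    genome.genes.extend([ga, gb])
    return PlantedFeature(
        kind="antisense_pair", scaffold=scaffold, start=pos, end=pos + total,
        strand="+",
        payload={"overlap": overlap, "gene_a": ga.gene_id,
                 "gene_b": gb.gene_id,
                 "below_min": overlap < thr.nat_min_overlap})


def _plant_contaminant(genome: SyntheticGenome, spec: dict,
                       rng: random.Random,
                       thr: Thresholds) -> PlantedFeature:
    label = spec.get("label", "tRNA")
    length = spec.get("length", 80 if label == "tRNA" else 150)
    seq = spec.get("sequence") or _random_seq(rng, length)
    scaffold, pos = _place(genome, len(seq), rng, spec.get("scaffold"),
                           spec.get("pos"))
    _overwrite(genome, scaffold, pos, seq)
    return PlantedFeature(
        kind="contaminant_gene", scaffold=scaffold, start=pos,
        end=pos + len(seq), strand="+",
        payload={"label": label, "sequence": seq})


def _plant_background_gene(genome: SyntheticGenome, spec: dict,
                           rng: random.Random,
                           thr: Thresholds) -> PlantedFeature:
    exon_len = spec.get("exon_length", 200)
    intron_len = spec.get("intron_length", 300)
    total = 2 * exon_len + intron_len
    scaffold, pos = _place(genome, total, rng, spec.get("scaffold"),
                           spec.get("pos"))
    k = len(genome.genes)
    gene = GeneModel(f"gene{k}", f"gene{k}.t1", scaffold,
                     spec.get("strand", "+"),
                     [(pos, pos + exon_len),
                      (pos + exon_len + intron_len, pos + total)])
    genome.genes.append(gene)
    return PlantedFeature(
        kind="background_gene", scaffold=scaffold, start=pos,
        end=pos + total, strand=gene.strand,
        payload={"gene_id": gene.gene_id, "intron":
                 (pos + exon_len, pos + exon_len + intron_len)})


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

#: log-normal multiplicity model parameters (heavy-tailed count histogram)
LOGNORMAL_MU = 0.0
LOGNORMAL_SIGMA = 2.5


def lognormal_count(rng: random.Random, mu: float = LOGNORMAL_MU,
                    sigma: float = LOGNORMAL_SIGMA,
                    minimum: int = 1) -> int:
    return max(minimum, round(math.exp(rng.gauss(mu, sigma))))


@dataclass
class SimulatedReads:
    """A simulated collapsed library with per-record provenance."""

    records: list[SeqRecord]
    origins: list[Optional[int]]  # index into genome.truth, None = noise
    total_reads: int = 0


def simulate_reads(genome: SyntheticGenome, depth: int = 10000,
                   noise_frac: float = 0.2, seed: int = 0) -> SimulatedReads:
    """Emit reads for every planted feature plus uniform noise.

    Planted features emit reads at their truth counts (log-normal when
    unspecified); noise reads are uniform random genome substrings of
    15-30 nt on either strand.  Deterministic for a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= noise_frac < 1.0:
        raise ValueError("noise_frac must be in [0, 1)")
    rng = random.Random(seed)
    records: list[SeqRecord] = []
    origins: list[Optional[int]] = []

    def emit(seq: str, count: int, origin: Optional[int], tag: str) -> None:
        records.append(SeqRecord(id=f"{tag}-count{count}", sequence=seq,
                                 count=count))
        origins.append(origin)

    for fi, feat in enumerate(genome.truth):
        tagbase = f"f{fi}_{feat.kind}"
        if feat.kind == "mirna_hairpin":
            mc = feat.payload["mature_count"] or lognormal_count(rng, minimum=3)
            sc = feat.payload["star_count"]
            if sc is None:
                sc = max(1, mc // rng.randint(3, 10))
            feat.payload["mature_count"] = mc
            feat.payload["star_count"] = sc
            emit(feat.payload["mature_seq"], mc, fi, tagbase + "_mature")
            if sc > 0:
                emit(feat.payload["star_seq"], sc, fi, tagbase + "_star")
        elif feat.kind == "phased_locus":
            for k, (seq, strand, _p) in enumerate(feat.payload["reads"]):
                emit(seq, rng.randint(1, 2), fi, f"{tagbase}_{k}")
        elif feat.kind == "repeat_copy":
            seq = genome.scaffolds[feat.scaffold][feat.start:feat.end]
            for k in range(5):
                n = rng.randint(18, 26)
                p = rng.randrange(len(seq) - n)
                emit(seq[p:p + n], lognormal_count(rng), fi, f"{tagbase}_{k}")
        elif feat.kind == "antisense_pair":
            s = genome.scaffolds[feat.scaffold]
            glen = feat.payload.get("gene_length", 300)
            for k in range(3):
                p = feat.start + rng.randrange(max(1, glen - 21))
                emit(revcomp(s[p:p + 21]), rng.randint(1, 3), fi,
                     f"{tagbase}_{k}")
        elif feat.kind == "contaminant_gene":
            seq = feat.payload["sequence"]
            for k in range(6):
                n = rng.randint(15, 30)
                p = rng.randrange(len(seq) - n)
                emit(seq[p:p + n], lognormal_count(rng, minimum=2),
                     fi, f"{tagbase}_{k}")
        # background_gene emits nothing by itself

    n_noise = round(depth * noise_frac)
    names = list(genome.scaffolds)
    for k in range(n_noise):
        name = rng.choice(names)
        s = genome.scaffolds[name]
        n = rng.randint(15, 30)
        p = rng.randrange(len(s) - n)
        seq = s[p:p + n]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        emit(seq, 1, None, f"noise{k}")

    lib = SimulatedReads(records=records, origins=origins)
    lib.total_reads = sum(r.count for r in records)
    return lib


# ---------------------------------------------------------------------------
# canned scenario
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    genome: SyntheticGenome
    reads: SimulatedReads
    contaminants: list[SeqRecord]
    repeats: list[tuple[str, int, int]]


def simulate_dataset(seed: int = 42, n_hairpins: int = 30,
                     n_phased: int = 4, n_repeat_copies: int = 5,
                     n_antisense: int = 2, n_contaminants: int = 2,
                     n_background_genes: int = 6,
                     n_scaffolds: int = 6, scaffold_len: int = 20000,
                     gc: float = 0.65, depth: int = 5000,
                     noise_frac: float = 0.2,
                     thresholds: Thresholds | None = None) -> Dataset:
    """Build the default truth-labelled scenario used by tests and the CLI."""
    thr = thresholds or Thresholds()
    rng = random.Random(seed)
    genome = build_genome(n_scaffolds, scaffold_len, gc, seed)
    for k in range(n_background_genes):
        plant_feature(genome, "background_gene",
                      {"strand": "+-"[k % 2]}, rng.randrange(2**31), thr)
    for _ in range(n_hairpins):
        plant_feature(genome, "mirna_hairpin",
                      {"mature_count": rng.randint(3, 200),
                       "star_count": rng.randint(1, 20)},
                      rng.randrange(2**31), thr)
    for _ in range(n_phased):
        plant_feature(genome, "phased_locus",
                      {"n_phased": rng.randint(6, 10),
                       "n_phased_antisense": rng.randint(0, 3)},
                      rng.randrange(2**31), thr)
    consensus = _random_seq(rng, 400)
    for _ in range(n_repeat_copies):
        plant_feature(genome, "repeat_copy",
                      {"consensus": consensus, "family": "rf1"},
                      rng.randrange(2**31), thr)
    for _ in range(n_antisense):
        plant_feature(genome, "antisense_pair", {"overlap": rng.randint(30, 80)},
                      rng.randrange(2**31), thr)
    for k in range(n_contaminants):
        plant_feature(genome, "contaminant_gene",
                      {"label": "tRNA" if k % 2 == 0 else "rRNA"},
                      rng.randrange(2**31), thr)
    reads = simulate_reads(genome, depth=depth, noise_frac=noise_frac,
                           seed=rng.randrange(2**31))
    contaminants = [
        SeqRecord(id=f"{f.payload['label']}_{i}", sequence=f.payload["sequence"])
        for i, f in enumerate(genome.truth) if f.kind == "contaminant_gene"]
    repeats = [(f.scaffold, f.start, f.end) for f in genome.truth
               if f.kind == "repeat_copy"]
    return Dataset(genome=genome, reads=reads, contaminants=contaminants,
                   repeats=repeats)
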