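"""miRNA target prediction in two modes, plus GO level-2 clustering.

Plant mode scans transcripts for near-perfect reverse complementarity
(mismatches weighted 1, G:U pairs 0.5) and screens surviving sites by
the energetic cost of opening the local secondary structure (UPE).
Animal mode requires a perfectly complementary seed (positions 2-8 from
the small RNA's 5' end) and a favorable intermolecular duplex energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from srnakit.config import Thresholds
from srnakit.read_processing import revcomp
from srnakit.rna_fold import duplex_energy, fold_constrained, fold_mfe, pairable

#: context window (nt) centered on a site for the opening-energy screen;
#: clipped at transcript ends
UPE_CONTEXT = 200


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # site interval on the transcript, 0-based half-open
    end: int
    mismatches: float  # weighted: full mismatch 1.0, G:U 0.5
    gu_pairs: int
    energy: float  # intermolecular duplex energy, kcal/mol
    upe: Optional[float]  # site-opening energy (plant mode only)
    mode: str  # 'plant' | 'animal'


def _site_score(mirna: str, window: str) -> tuple[float, int]:
    """Weighted mismatches and G:U count for miRNA vs a target window.

    The window is the transcript site 5'->3'; the miRNA pairs it
    antiparallel, so miRNA position k faces window position L-1-k.
    """
    mism = 0.0
    gu = 0
    L = len(mirna)
    for k in range(L):
        mi, tb = mirna[k], window[L - 1 - k]
        if (mi, tb) in (("G", "T"), ("T", "G")):
            mism += 0.5
            gu += 1
        elif not pairable(mi, tb):
            mism += 1.0
    return mism, gu


def plant_targets(mirna: str, transcripts, thresholds: Thresholds,
                  mirna_id: str = "mirna",
                  upe_context: int = UPE_CONTEXT) -> list[TargetSite]:
    """Plant-mode sites: weighted mismatches <= plant_max_mismatch and
    opening energy (UPE) <= plant_max_upe.

    Overlapping sites on one transcript are merged to the best-scoring
    one (lowest weighted mismatches, then lowest UPE).
    """
    mirna = mirna.upper().replace("U", "T")
    L = len(mirna)
    out: list[TargetSite] = []
    for tx in transcripts:
        seq = tx.sequence
        raw: list[TargetSite] = []
        for s in range(0, len(seq) - L + 1):
            window = seq[s:s + L]
            mism, gu = _site_score(mirna, window)
            if mism > thresholds.plant_max_mismatch:
                continue
            half = upe_context // 2
            cs = max(0, s + L // 2 - half)
            ce = min(len(seq), cs + upe_context)
            context = seq[cs:ce]
            upe = (fold_constrained(context, (s - cs, s + L - cs)).energy
                   - fold_mfe(context).energy)
            if upe > thresholds.plant_max_upe:
                continue
            raw.append(TargetSite(
                mirna_id, tx.id, s, s + L, mism, gu,
                duplex_energy(mirna, window), round(upe, 6), "plant"))
        out.extend(_merge_overlapping(raw))
    return out


def animal_targets(mirna: str, transcripts, thresholds: Thresholds,
                   mirna_id: str = "mirna") -> list[TargetSite]:
    """Animal-mode sites: perfect seed (positions 2-8) complement in the
    transcript and duplex energy < animal_max_energy."""
    mirna = mirna.upper().replace("U", "T")
    L = len(mirna)
    seed = mirna[thresholds.animal_seed_start - 1:thresholds.animal_seed_end]
    seed_rc = revcomp(seed)
    out: list[TargetSite] = []
    for tx in transcripts:
        seq = tx.sequence
        raw: list[TargetSite] = []
        pos = seq.find(seed_rc)
        while pos >= 0:
            # seed_rc occupies transcript [pos, pos+len); the full site
            # extends so the miRNA covers it antiparallel
            end = pos + len(seed_rc) + (thresholds.animal_seed_start - 1)
            start = end - L
            if start >= 0 and end <= len(seq):
                window = seq[start:end]
                energy = duplex_energy(mirna, window)
                if energy < thresholds.animal_max_energy:
                    mism, gu = _site_score(mirna, window)
                    raw.append(TargetSite(mirna_id, tx.id, start, end,
                                          mism, gu, energy, None, "animal"))
            pos = seq.find(seed_rc, pos + 1)
        out.extend(_merge_overlapping(raw))
    return out


def _merge_overlapping(sites: list[TargetSite]) -> list[TargetSite]:
    """One biological site, many alignments: keep the best per overlap
    group (lowest mismatches, then lowest duplex energy)."""
    kept: list[TargetSite] = []
    for site in sorted(sites, key=lambda s: (s.mismatches, s.energy, s.start)):
        if not any(site.start < k.end and site.end > k.start for k in kept):
            kept.append(site)
    return sorted(kept, key=lambda s: s.start)


# ---------------------------------------------------------------------------
# GO level-2 clustering
# ---------------------------------------------------------------------------

class OntologyError(ValueError):
    pass


def go_level2_clusters(gene_to_terms: dict[str, list[str]],
                       ontology: list[tuple[str, str]]) -> dict[str, set[str]]:
    """Cluster genes under level-2 ontology terms.

    ``ontology`` is a child->parent edge list; roots are terms that
    appear only as parents.  Level-2 terms are the direct children of a
    root.  A gene joins the cluster of every level-2 term that is an
    ancestor (or the term itself) of any of its annotations, so genes
    may join multiple clusters.  Raises on cyclic ontologies.
    """
    parents: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for child, parent in ontology:
        parents.setdefault(child, set()).add(parent)
        nodes.update((child, parent))
    roots = {n for n in nodes if not parents.get(n)}
    level2 = {child for child, ps in parents.items() if ps & roots}

    ancestors_cache: dict[str, set[str]] = {}

    def ancestors(term: str, trail: tuple[str, ...] = ()) -> set[str]:
        if term in trail:
            raise OntologyError(f"ontology cycle through {term!r}")
        if term not in ancestors_cache:
            acc = {term}
            for p in parents.get(term, ()):
                acc |= ancestors(p, trail + (term,))
            ancestors_cache[term] = acc
        return ancestors_cache[term]

    clusters: dict[str, set[str]] = {t: set() for t in sorted(level2)}
    for gene, terms in gene_to_terms.items():
        for term in terms:
            if term not in nodes:
                continue
            for anc in ancestors(term) & level2:
                clusters[anc].add(gene)
    return {t: genes for t, genes in clusters.items() if genes}
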