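"""Exact-match placement of short reads on both genome strands.

A fixed-k seed table plus verification: reads are 15-30 nt and only
exact occurrences matter, so a hash of every k-mer position per scaffold
is simpler and faster at desk scale than a full-text index.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from srnakit.read_processing import UniqueRead, revcomp

#: reads mapping to more loci than this are flagged hyper-repetitive and
#: excluded from miRNA discovery (kept for repeat-class analyses)
HYPER_REPETITIVE_CAP = 1000


@dataclass(frozen=True, order=True)
class Hit:
    scaffold: str
    start: int
    end: int  # half-open
    strand: str  # '+' or '-'
    read: str  # the read sequence (as sequenced)


class GenomeIndex:
    """k-mer seed table over a dict of scaffold sequences."""

    def __init__(self, scaffolds: dict[str, str], k: int = 12):
        if k < 1:
            raise ValueError("seed length k must be >= 1")
        self.k = k
        self.scaffolds = {name: seq.upper() for name, seq in scaffolds.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.scaffolds.items():
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i:i + k]].append((name, i))

    def map_exact(self, read: UniqueRead | str) -> list[Hit]:
        """All exact occurrences of the read on both strands.

        Sorted by (scaffold, start, strand); multi-mapping preserved.
        """
        seq = read.sequence if isinstance(read, UniqueRead) else read.upper()
        if len(seq) < self.k:
            raise ValueError(f"read shorter than seed length k={self.k}")
        hits = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for name, i in self._seeds.get(query[:self.k], ()):
                if self.scaffolds[name][i:i + len(query)] == query:
                    hits.append(Hit(name, i, i + len(query), strand, seq))
        return sorted(hits, key=lambda h: (h.scaffold, h.start, h.strand))


def build_index(scaffolds: dict[str, str], k: int = 12) -> GenomeIndex:
    return GenomeIndex(scaffolds, k)


def map_exact(index: GenomeIndex, read) -> list[Hit]:
    return index.map_exact(read)


def map_library(index: GenomeIndex, reads,
                cap: int = HYPER_REPETITIVE_CAP):
    """Map a collapsed library; returns (hits_by_read, hyper_repetitive).

    ``hits_by_read`` maps each read sequence to its hit list; reads with
    more than ``cap`` loci go to the hyper-repetitive set instead.
    """
    hits_by_read: dict[str, list[Hit]] = {}
    hyper: dict[str, list[Hit]] = {}
    for r in reads:
        hits = index.map_exact(r)
        if not hits:
            continue
        (hyper if len(hits) > cap else hits_by_read)[r.sequence] = hits
    return hits_by_read, hyper
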