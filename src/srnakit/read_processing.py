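"""Collapse raw reads to unique sequences and apply library filters."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from srnakit.io_formats import SeqRecord


@dataclass(frozen=True, order=True)
class UniqueRead:
    sequence: str
    count: int

    def __len__(self) -> int:
        return len(self.sequence)


def collapse(reads) -> list[UniqueRead]:
    """Collapse sequence records into unique reads with summed counts.

    Multiplicities on the input records are honored, so the sum of the
    output counts equals the total input read count.  Output is ordered
    by descending count, then lexicographically.
    """
    counter: Counter[str] = Counter()
    for rec in reads:
        if isinstance(rec, SeqRecord):
            counter[rec.sequence] += rec.count
        elif isinstance(rec, UniqueRead):
            counter[rec.sequence] += rec.count
        else:
            counter[str(rec).upper().replace("U", "T")] += 1
    return [UniqueRead(seq, n)
            for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))]


def filter_reads(reads, len_range: tuple[int, int], contaminants=(),
                 containment: bool = True,
                 both_strands: bool = True) -> list[UniqueRead]:
    """Keep reads inside ``len_range`` that are not contaminant matches.

    A read is a contaminant match when it equals a contaminant sequence
    (``containment=False``) or occurs as an exact substring of one
    (``containment=True``, the default: small RNAs are fragments of the
    tRNA/rRNA molecules they derive from, so whole-sequence equality
    would remove almost nothing).  With ``both_strands`` the reverse
    complement is also queried.  Counts are unchanged on survivors and
    the operation is idempotent.
    """
    lo, hi = len_range
    contam = [c.sequence if hasattr(c, "sequence") else str(c).upper().replace("U", "T")
              for c in contaminants]

    def is_contaminant(seq: str) -> bool:
        queries = [seq]
        if both_strands:
            queries.append(revcomp(seq))
        for q in queries:
            for c in contam:
                if (containment and q in c) or (not containment and q == c):
                    return True
        return False

    return [r for r in reads
            if lo <= len(r.sequence) <= hi and not is_contaminant(r.sequence)]


def length_histogram(reads, weighted: bool = False,
                     len_range: tuple[int, int] = (15, 30)) -> dict[int, int]:
    """Counts per read length; weighted sums library counts, else uniques."""
    lo, hi = len_range
    hist = {n: 0 for n in range(lo, hi + 1)}
    for r in reads:
        n = len(r.sequence)
        if lo <= n <= hi:
            hist[n] += r.count if weighted else 1
    return hist


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
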