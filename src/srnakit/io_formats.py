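"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open with explicit strand
everywhere; conversion to/from the 1-based inclusive GFF3 convention
happens only at the I/O boundary.  Collapsed read libraries travel as
FASTA with a ``-countN`` header suffix carrying the multiplicity.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_COUNT_RE = re.compile(r"-count(\d+)$")


class ParseError(ValueError):
    pass


@dataclass
class SeqRecord:
    """A sequence record with collapsed-library multiplicity."""

    id: str
    sequence: str  # uppercase DNA (U normalized to T)
    count: int = 1
    rna_origin: bool = False  # input contained U

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with its exon chain, in internal 0-based half-open coords."""

    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[k][1], ex[k + 1][0]) for k in range(len(ex) - 1)]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"gene {self.gene_id}: strand must be + or -, "
                             f"got {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ParseError(f"gene {self.gene_id}: overlapping exons")
        for s, e in ex:
            if s >= e:
                raise ParseError(f"gene {self.gene_id}: empty exon [{s},{e})")


def _normalize(seq: str) -> tuple[str, bool]:
    up = seq.upper()
    rna = "U" in up
    return up.replace("U", "T"), rna


def _record_from(name: str, seq: str) -> SeqRecord:
    m = _COUNT_RE.search(name)
    count = int(m.group(1)) if m else 1
    norm, rna = _normalize(seq)
    return SeqRecord(id=name, sequence=norm, count=count, rna_origin=rna)


def read_sequences(path: str | Path, format: str = "fasta") -> list[SeqRecord]:
    """Read FASTA/FASTQ records, preserving order.

    Sequences are uppercased and U->T normalized (flagged per record);
    a ``-countN`` suffix on the header is parsed as the multiplicity.
    """
    path = Path(path)
    if format == "fasta":
        return [_record_from(rec.id, str(rec.seq))
                for rec in SeqIO.parse(str(path), "fasta")]
    if format == "fastq":
        return _read_fastq(path)
    raise ValueError(f"unknown sequence format {format!r}")


def _read_fastq(path: Path) -> list[SeqRecord]:
    records = []
    lines = path.read_text().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ quartet at line {len(lines)}")
    for q in range(0, len(lines), 4):
        head, seq, plus, qual = lines[q:q + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}: line {q + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {q + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(f"{path}: line {q + 4}: quality length mismatch")
        records.append(_record_from(head[1:].split()[0], seq))
    return records


def write_sequences(records, path: str | Path, with_counts: bool = True) -> None:
    """Write records as FASTA; multiplicity becomes a ``-countN`` suffix."""
    with open(path, "w") as fh:
        for rec in records:
            name = rec.id
            if with_counts and not _COUNT_RE.search(name):
                name = f"{name}-count{rec.count}"
            fh.write(f">{name}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, format: str = "gff3"):
    """Read GFF3 gene models or a BED3+ interval list.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open; BED is taken as already 0-based half-open.
    """
    if format == "bed":
        return read_bed(path)
    if format == "gff3":
        return read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_bed(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def _gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for kv in s.strip().split(";"):
        if kv and "=" in kv:
            k, _, v = kv.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    tx_to_gene: dict[str, str] = {}
    pending_exons: list[tuple[str, str, int, int, str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
        scaffold, _, ftype, start, end, _, strand, _, attrs = cols
        s, e = int(start) - 1, int(end)  # to 0-based half-open
        a = _gff_attrs(attrs)
        if ftype == "gene":
            gid = a.get("ID", f"gene{lineno}")
            genes[gid] = GeneModel(gid, gid, scaffold, strand, [])
        elif ftype == "mRNA":
            tx_to_gene[a.get("ID", "")] = a.get("Parent", "")
        elif ftype == "exon":
            parent = a.get("Parent", "")
            pending_exons.append((scaffold, parent, s, e, strand, lineno))
    for scaffold, parent, s, e, strand, lineno in pending_exons:
        gid = tx_to_gene.get(parent, parent)
        if gid not in genes:
            raise ParseError(f"{path}:{lineno}: exon parent {parent!r} has no "
                             f"declared gene")
        gene = genes[gid]
        if strand == ".":
            raise ParseError(f"{path}:{lineno}: exon requires explicit strand")
        if strand != gene.strand or scaffold != gene.scaffold:
            raise ParseError(f"{path}:{lineno}: exon disagrees with parent "
                             f"gene {gid}")
        gene.exons.append((s, e))
    models = [g for g in genes.values() if g.exons]
    for g in models:
        g.exons.sort()
        g.validate()
    return models


def write_gff3(genes, path: str | Path, extra_records=()) -> None:
    """Write gene/mRNA/exon rows (plus optional pre-built rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            base = f"{g.scaffold}\tsrnakit\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(f"{base}gene\t{s + 1}\t{e}{tail}\tID={g.gene_id}\n")
            fh.write(f"{base}mRNA\t{s + 1}\t{e}{tail}\tID={g.transcript_id};"
                     f"Parent={g.gene_id}\n")
            for (xs, xe) in g.exons:
                fh.write(f"{base}exon\t{xs + 1}\t{xe}{tail}\t"
                         f"Parent={g.transcript_id}\n")
        for row in extra_records:
            fh.write(row.rstrip("\n") + "\n")


# ---------------------------------------------------------------------------
# tabular reports
# ---------------------------------------------------------------------------

def write_report(records, path: str | Path, columns=None) -> None:
    """Write a homogeneous record table as TSV with a header row.

    Records may be dataclasses, dicts, or named tuples; the column order
    is taken from the first record (or ``columns``) and is deterministic.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            rows.append(rec)
        elif hasattr(rec, "_asdict"):
            rows.append(rec._asdict())
        else:
            raise TypeError(f"unsupported record type {type(rec)!r}")
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                extrasaction="ignore", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def read_report(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
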