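"""Interval/annotation data model and readers/writers.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based, closed) is converted on read. Fragments are counted strandless:
MeDIP/ChIP fragments are double-stranded and strand carries no signal here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised for malformed annotation or interval files."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if length <= 0:
                raise ValueError(f"length of {name!r} must be > 0, got {length}")

    @classmethod
    def read(cls, path: str | Path) -> "ChromSizes":
        sizes: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected two tab-separated columns")
            name = parts[0]
            if name in sizes:
                raise ParseError(f"{path}:{i}: duplicate chromosome {name!r}")
            sizes[name] = int(parts[1])
        return cls(sizes)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{l}\n" for c, l in self.items())
        )


@dataclass
class GeneModel:
    """Stranded gene with exons and a strand-aware TSS.

    ``tss`` is body.start on the plus strand and body.end - 1 on the minus
    strand (the 5' base in genomic coordinates).
    """

    gene_id: str
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.body.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.body.chrom or ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon {ex} outside body {self.body}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        if self.body.strand == "+":
            return self.body.start
        return self.body.end - 1

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass
class FragmentSet:
    """Strandless sequenced fragments plus the library size used downstream."""

    fragments: list[GenomicInterval]

    @property
    def total_mapped(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


def read_intervals(path: str | Path, sizes: ChromSizes) -> FragmentSet:
    """Read BED3/BED6 intervals; drop records on chromosomes absent from ``sizes``.

    Dropped records are logged with a count; malformed lines raise
    :class:`ParseError` naming the line number.
    """
    kept: list[GenomicInterval] = []
    dropped = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: expected >= 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if end <= start:
                raise ParseError(f"{path}:{i}: end ({end}) <= start ({start})")
            if chrom not in sizes:
                dropped += 1
                continue
            kept.append(GenomicInterval(chrom, start, end))
    if dropped:
        log.info("read_intervals(%s): dropped %d records on unknown chromosomes", path, dropped)
    return FragmentSet(kept)


def _genes_from_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{i}: BED12 requires 12 columns, got {len(parts)}")
            chrom, start, end, name, _, strand = parts[:6]
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{i}: missing or invalid strand {strand!r}")
            start, end = int(start), int(end)
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{i}: block count mismatch")
            body = GenomicInterval(chrom, start, end, strand)
            exons = [
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            ]
            genes.append(GeneModel(name, body, exons))
    return genes


def _genes_from_gtf(path: str | Path) -> list[GeneModel]:
    import re

    gene_id_re = re.compile(r'gene_id\s+"([^"]+)"')
    exons: dict[str, list[GenomicInterval]] = {}
    bodies: dict[str, GenomicInterval] = {}
    order: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{i}: GTF requires 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = parts[:9]
            if feature not in {"gene", "transcript", "exon"}:
                continue
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{i}: missing or invalid strand {strand!r}")
            m = gene_id_re.search(attrs)
            if not m:
                raise ParseError(f"{path}:{i}: no gene_id attribute")
            gid = m.group(1)
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            if gid not in exons:
                exons[gid] = []
                order.append(gid)
            if feature == "gene":
                bodies[gid] = iv
            elif feature == "exon":
                exons[gid].append(iv)
    genes = []
    for gid in order:
        exs = exons[gid]
        if gid in bodies:
            body = bodies[gid]
        elif exs:
            body = GenomicInterval(
                exs[0].chrom, min(e.start for e in exs), max(e.end for e in exs), exs[0].strand
            )
        else:
            continue
        # collapse exons shared across transcripts to a disjoint union
        merged: list[GenomicInterval] = []
        for ex in sorted(exs, key=lambda e: e.start):
            if merged and ex.start <= merged[-1].end:
                last = merged[-1]
                merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, ex.end), last.strand)
            else:
                merged.append(ex)
        try:
            genes.append(GeneModel(gid, body, merged))
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    return genes


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 or GTF file (sniffed by content)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gtf", ".gff"}:
        return _genes_from_gtf(path)
    if suffix.startswith(".bed"):
        return _genes_from_bed12(path)
    # sniff: GTF has '"' in attribute column and 1-based feature column
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                ncol = len(line.rstrip("\n").split("\t"))
                return _genes_from_gtf(path) if ncol == 9 else _genes_from_bed12(path)
    return []


def write_genes_bed12(genes: list[GeneModel], path: str | Path) -> None:
    """Serialize gene models as BED12 (used by `epiwindow convert`)."""
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [g.body]
            sizes = ",".join(str(len(e)) for e in exons) + ","
            starts = ",".join(str(e.start - g.body.start) for e in exons) + ","
            fh.write(
                f"{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.body.start}\t{g.body.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def write_intervals(frags: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in frags:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
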