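"""Unique assignment of sequenced fragments to repeat annotations, per-type
aggregation, and depth normalization.

Each fragment (a read pair collapsed to its outer span, or a singleton) is
assigned to at most one repeat location: the overlapping annotation with the
largest overlap, ties going to the repeat with the smallest (chrom, start).
Counts are summed per repeat subfamily and scaled per million mapped
fragments; differential testing on the count matrix is delegated to external
count-model tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .core_io import FragmentSet, GenomicInterval, ParseError

REPEAT_CLASSES = ("LTR", "LINE", "SINE", "other")


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    subfamily: str
    family: str
    repeat_class: str


@dataclass
class RepeatAnnotation:
    records: list[RepeatRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def read_bed(cls, path: str | Path) -> "RepeatAnnotation":
        """BED with name field "subfamily|family|class"; paired-internal
        subfamilies may carry the "LTRname::internal-name" form."""
        records = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{i}: repeat BED requires >= 4 columns")
                fields = parts[3].split("|")
                if len(fields) != 3:
                    raise ParseError(f"{path}:{i}: name must be subfamily|family|class")
                sub, fam, cls_ = fields
                records.append(
                    RepeatRecord(
                        GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                        sub,
                        fam,
                        cls_ if cls_ in REPEAT_CLASSES else "other",
                    )
                )
        return cls(records)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                iv = r.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.subfamily}|{r.family}|{r.repeat_class}\t0\t.\n"
                )


def pair_span(mate1: GenomicInterval, mate2: GenomicInterval) -> GenomicInterval:
    """Collapse a read pair to one counting unit spanning its outer coordinates."""
    if mate1.chrom != mate2.chrom:
        raise ValueError("mates on different chromosomes cannot form a counting unit")
    return GenomicInterval(mate1.chrom, min(mate1.start, mate2.start), max(mate1.end, mate2.end))


def assign_to_repeats(
    frags: FragmentSet, repeats: RepeatAnnotation
) -> list[int | None]:
    """Per fragment, the index of the uniquely assigned repeat (or None).

    Assignment: maximal overlap length; ties broken by the repeat's
    (chrom, start, end, index-independent) genomic coordinate so results do
    not depend on annotation order.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, rec in enumerate(repeats):
        iv = rec.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    out: list[int | None] = []
    for frag in frags:
        tree = trees.get(frag.chrom)
        if tree is None:
            out.append(None)
            continue
        best: tuple[float, tuple, int] | None = None
        for hit in tree.overlap(frag.start, frag.end):
            ovl = min(hit.end, frag.end) - max(hit.begin, frag.start)
            rec = repeats.records[hit.data]
            key = (-ovl, (rec.interval.chrom, rec.interval.start, rec.interval.end), hit.data)
            if best is None or key < best:
                best = key
        out.append(best[2] if best else None)
    return out


def count_by_type(
    assignments: list[int | None], repeats: RepeatAnnotation, sample: str = "sample"
) -> pd.DataFrame:
    """Sum assigned fragments per repeat subfamily (one column per sample)."""
    counts: dict[str, int] = {}
    for idx in assignments:
        if idx is None:
            continue
        sub = repeats.records[idx].subfamily
        counts[sub] = counts.get(sub, 0) + 1
    return pd.DataFrame({sample: pd.Series(counts, dtype=int)}).sort_index()


def combine_counts(per_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-sample count columns into a repeat_type x sample matrix."""
    mat = pd.concat([df[name] for name, df in per_sample.items()], axis=1)
    return mat.fillna(0).astype(int).sort_index()


def normalize_repeat_counts(
    counts: pd.DataFrame, totals: dict[str, int], scale: float = 1e6
) -> pd.DataFrame:
    """Per-million-mapped normalization: count * scale / total_mapped."""
    out = counts.astype(float).copy()
    for sample in counts.columns:
        total = totals[sample]
        if total <= 0:
            raise ValueError(f"total_mapped for {sample!r} must be > 0")
        out[sample] = counts[sample] * scale / total
    return out


def class_rollup(counts: pd.DataFrame, repeats: RepeatAnnotation) -> pd.DataFrame:
    """Sum subfamily counts up to repeat class (LTR/LINE/SINE/other)."""
    cls_of = {r.subfamily: r.repeat_class for r in repeats}
    grouped = counts.groupby([cls_of.get(s, "other") for s in counts.index]).sum()
    grouped.index.name = "repeat_class"
    return grouped
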