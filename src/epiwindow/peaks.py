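"""Percentile-threshold peak calling and genomic-compartment assignment.

Peaks are regions where at least 2 of 3 consecutive 200 bp windows exceed a
threshold taken as the 95th percentile (nearest-rank) of positive window
scores from a designated reference sample; the threshold is computed once on
the reference and reused verbatim for every other sample. Called peaks are
mapped to one of six genomic compartments in strict precedence order:
promoter core (TSS +/-100 bp) > promoter proximal (within 1 kb) > promoter
distal (1-2 kb) > exonic > intronic > intergenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import GeneModel, GenomicInterval, ParseError
from .windows import WindowTrack

COMPARTMENTS = (
    "promoter_core",
    "promoter_proximal",
    "promoter_distal",
    "exonic",
    "intronic",
    "intergenic",
)


@dataclass(frozen=True)
class Threshold:
    value: float
    percentile: float = 95.0
    reference_name: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold value must be >= 0")


@dataclass
class Peak:
    interval: GenomicInterval
    compartment: str = "unassigned"
    n_qualifying_windows: int = 0


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def compartment_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in COMPARTMENTS}
        for p in self.peaks:
            counts.setdefault(p.compartment, 0)
            counts[p.compartment] += 1
        return counts


def reference_threshold(ref: WindowTrack, percentile: float = 95.0) -> Threshold:
    """Nearest-rank percentile of the reference track's positive window scores.

    Zero windows are excluded: on sparse genome-wide data the zero-inflated
    majority would drag any percentile to 0.
    """
    positives = np.concatenate([a[a > 0] for a in ref.scores.values()]) if ref.scores else np.array([])
    if positives.size == 0:
        raise ValueError("no enriched signal in reference")
    positives.sort()
    rank = math.ceil(percentile / 100.0 * positives.size)
    rank = min(max(rank, 1), positives.size)
    return Threshold(float(positives[rank - 1]), percentile)


def call_peaks(
    track: WindowTrack,
    thr: Threshold,
    region_windows: int = 3,
    min_qualifying: int = 2,
) -> PeakSet:
    """Mark every ``region_windows``-window run holding >= ``min_qualifying``
    windows strictly above the threshold, then merge overlapping or
    book-ended marked spans into maximal peaks."""
    if region_windows < min_qualifying:
        raise ValueError("region_windows must be >= min_qualifying")
    peaks: list[Peak] = []
    w = track.grid.window_size
    for chrom in track.grid.chroms:
        arr = track.scores[chrom]
        n = arr.shape[0]
        qual = arr > thr.value
        if n < region_windows:
            continue
        # window-index spans fired by the run rule
        hits = np.convolve(qual.astype(int), np.ones(region_windows, dtype=int), "valid")
        fired = np.nonzero(hits >= min_qualifying)[0]
        if fired.size == 0:
            continue
        # merge overlapping/book-ended [i, i+region_windows) spans
        chrom_len = track.grid.sizes[chrom]
        span_start, span_end = fired[0], fired[0] + region_windows
        for i in fired[1:]:
            if i <= span_end:
                span_end = i + region_windows
            else:
                peaks.append(_make_peak(chrom, span_start, span_end, w, chrom_len, qual))
                span_start, span_end = i, i + region_windows
        peaks.append(_make_peak(chrom, span_start, span_end, w, chrom_len, qual))
    return PeakSet(peaks)


def _make_peak(chrom: str, wi0: int, wi1: int, w: int, chrom_len: int, qual: np.ndarray) -> Peak:
    start = wi0 * w
    end = min(wi1 * w, chrom_len)
    return Peak(
        GenomicInterval(chrom, start, end),
        n_qualifying_windows=int(qual[wi0:wi1].sum()),
    )


def _promoter_window(gene: GeneModel, flank: int, side: str) -> GenomicInterval:
    """Interval covered by "TSS +/- flank" (symmetric) or the directional
    reading "TSS + flank" (downstream in the transcription direction)."""
    t = gene.tss
    if side == "symmetric":
        start, end = t - flank, t + flank + 1
    elif side == "downstream":
        if gene.strand == "+":
            start, end = t, t + flank + 1
        else:
            start, end = t - flank, t + 1
    else:
        raise ValueError(f"unknown promoter side {side!r}")
    return GenomicInterval(gene.chrom, max(start, 0), end)


def assign_compartments(
    peaks: PeakSet,
    genes: list[GeneModel],
    core_bp: int = 100,
    proximal_bp: int = 1000,
    distal_bp: int = 2000,
    promoter_side: str = "symmetric",
) -> PeakSet:
    """Label each peak with the highest-precedence compartment it overlaps.

    Precedence: promoter_core > promoter_proximal > promoter_distal > exonic
    > intronic > intergenic. Promoter windows are strand-aware around each
    gene's TSS; a peak overlapping features of several genes resolves purely
    by precedence.
    """
    layers: list[tuple[str, list[GenomicInterval]]] = [
        ("promoter_core", [_promoter_window(g, core_bp, promoter_side) for g in genes]),
        ("promoter_proximal", [_promoter_window(g, proximal_bp, promoter_side) for g in genes]),
        ("promoter_distal", [_promoter_window(g, distal_bp, promoter_side) for g in genes]),
        ("exonic", [e for g in genes for e in g.exons]),
        ("intronic", [g.body for g in genes]),
    ]
    for peak in peaks:
        label = "intergenic"
        for name, ivs in layers:
            if any(peak.interval.overlap_len(iv) > 0 for iv in ivs):
                label = name
                break
        peak.compartment = label
    return peaks


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """BED6: name = compartment, score = number of qualifying windows."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.compartment}\t{p.n_qualifying_windows}\t.\n"
            )


def read_peaks(path: str | Path) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{i}: peak BED requires 6 columns")
            peaks.append(
                Peak(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    compartment=parts[3],
                    n_qualifying_windows=int(parts[4]),
                )
            )
    return PeakSet(peaks)
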