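"""Average signal profiles over genomic features, stratified gene sets,
nearest-gene mapping for distal TF sites, and consensus differential sets.

Profiles realize the "sliding window" averaging as fixed binning: a feature's
span is cut into equal bins and each bin takes the per-base-pair mean of the
underlying window step function (overlap-length-weighted window average).
Minus-strand features are reversed so bin 0 is always the 5'/upstream end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomicInterval
from .peaks import PeakSet
from .windows import WindowTrack


@dataclass
class MetaProfile:
    feature_class: str
    bins: list[str]
    per_feature_matrix: np.ndarray  # feature x bin, NaN where no coverage
    feature_ids: list[str]

    @property
    def n_features(self) -> int:
        return self.per_feature_matrix.shape[0]

    @property
    def mean_signal(self) -> np.ndarray:
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
            return np.nanmean(self.per_feature_matrix, axis=0)

    def to_frame(self) -> pd.DataFrame:
        n = np.sum(~np.isnan(self.per_feature_matrix), axis=0)
        return pd.DataFrame({"bin": self.bins, "mean": self.mean_signal, "n": n})


def _segment_bin_values(
    track: WindowTrack, chrom: str, a: float, b: float, n_bins: int
) -> np.ndarray:
    """Per-bp mean of the window step function over each of ``n_bins`` equal
    bins of [a, b); bins with no overlap with the chromosome are NaN."""
    arr = track.scores[chrom]
    w = track.grid.window_size
    length = track.grid.sizes[chrom]
    binw = (b - a) / n_bins
    out = np.full(n_bins, np.nan)
    for k in range(n_bins):
        lo = max(a + k * binw, 0.0)
        hi = min(a + (k + 1) * binw, float(length))
        if hi <= lo:
            continue
        i0, i1 = int(lo // w), int(math.ceil(hi / w))
        i1 = min(i1, arr.shape[0])
        total = 0.0
        weight = 0.0
        for i in range(i0, i1):
            ovl = min((i + 1) * w, hi, float(length)) - max(i * w, lo)
            if ovl > 0:
                total += arr[i] * ovl
                weight += ovl
        if weight > 0:
            out[k] = total / weight
    return out


def _feature_profile(
    track: WindowTrack,
    chrom: str,
    strand: str,
    segments: list[tuple[float, float, int]],
) -> np.ndarray:
    vals = np.concatenate(
        [_segment_bin_values(track, chrom, a, b, nb) for a, b, nb in segments]
    )
    if strand == "-":
        vals = vals[::-1]
    return vals


def promoter_profile(
    track: WindowTrack, genes: list[GeneModel], flank: int = 2000, n_bins: int = 40
) -> MetaProfile:
    """Mean signal over TSS +/- ``flank``, in ``n_bins`` equal bins,
    strand-flipped so bin 0 is upstream."""
    if n_bins % 2:
        raise ValueError("n_bins must be even")
    rows, ids = [], []
    for g in genes:
        t = g.tss
        a, b = (t - flank, t + flank) if g.strand == "+" else (t + 1 - flank, t + 1 + flank)
        row = _feature_profile(track, g.chrom, g.strand, [(a, b, n_bins)])
        if np.all(np.isnan(row)):
            continue
        rows.append(row)
        ids.append(g.gene_id)
    binw = 2 * flank / n_bins
    labels = [f"{int(-flank + k * binw)}:{int(-flank + (k + 1) * binw)}" for k in range(n_bins)]
    return MetaProfile("promoter", labels, np.array(rows).reshape(len(rows), n_bins), ids)


def genebody_profile(
    track: WindowTrack,
    genes: list[GeneModel],
    flank_fraction: float = 0.25,
    body_bins: int = 100,
    flank_bins: int = 25,
) -> MetaProfile:
    """Length-normalized gene bodies with flanks of ``flank_fraction`` x gene
    length on each side (5' flank first, strand-aware)."""
    rows, ids = [], []
    for g in genes:
        s, e = g.body.start, g.body.end
        if e <= s:
            raise ValueError(f"gene {g.gene_id} has zero length")
        fl = flank_fraction * (e - s)
        segs = [(s - fl, s, flank_bins), (float(s), float(e), body_bins), (float(e), e + fl, flank_bins)]
        row = _feature_profile(track, g.chrom, g.strand, segs)
        if np.all(np.isnan(row)):
            continue
        rows.append(row)
        ids.append(g.gene_id)
    labels = (
        [f"up_{k}" for k in range(flank_bins)]
        + [f"body_{k}" for k in range(body_bins)]
        + [f"down_{k}" for k in range(flank_bins)]
    )
    return MetaProfile("genebody", labels, np.array(rows).reshape(len(rows), len(labels)), ids)


def element_profile(
    track: WindowTrack,
    elements: list[GenomicInterval],
    flank_fraction: float = 1.0,
    bins_per_segment: int = 25,
) -> MetaProfile:
    """Scaled element bodies with flanks of ``flank_fraction`` x element length."""
    if not elements:
        raise ValueError("element list is empty")
    rows, ids = [], []
    for j, el in enumerate(elements):
        fl = flank_fraction * len(el)
        segs = [
            (el.start - fl, float(el.start), bins_per_segment),
            (float(el.start), float(el.end), bins_per_segment),
            (float(el.end), el.end + fl, bins_per_segment),
        ]
        strand = el.strand if el.strand in {"+", "-"} else "+"
        row = _feature_profile(track, el.chrom, strand, segs)
        if np.all(np.isnan(row)):
            continue
        rows.append(row)
        ids.append(f"element_{j}")
    labels = (
        [f"up_{k}" for k in range(bins_per_segment)]
        + [f"body_{k}" for k in range(bins_per_segment)]
        + [f"down_{k}" for k in range(bins_per_segment)]
    )
    return MetaProfile("element", labels, np.array(rows).reshape(len(rows), len(labels)), ids)


def promoter_mean(track: WindowTrack, genes: list[GeneModel], flank: int = 1000) -> pd.Series:
    """Per-gene overlap-weighted mean window score over TSS +/- ``flank``."""
    out = {}
    for g in genes:
        t = g.tss
        vals = _segment_bin_values(track, g.chrom, t - flank, t + flank + 1, 1)
        out[g.gene_id] = float(vals[0])
    return pd.Series(out, name="promoter_mean")


def quartile_stratify(genes: list[GeneModel], expression: pd.Series) -> dict[str, list[str]]:
    """Partition genes into expression quartiles Q1 (high) .. Q4 (low).

    Sizes differ by at most one (larger quartiles first); ties broken by
    gene_id lexicographic order.
    """
    ids = [g.gene_id for g in genes]
    missing = [i for i in ids if i not in expression.index]
    if missing:
        raise ValueError(f"expression missing for genes: {missing[:5]}")
    ranked = sorted(ids, key=lambda i: (-float(expression[i]), i))
    n = len(ranked)
    base, rem = divmod(n, 4)
    sets: dict[str, list[str]] = {}
    pos = 0
    for q in range(4):
        size = base + (1 if q < rem else 0)
        sets[f"Q{q + 1}"] = ranked[pos : pos + size]
        pos += size
    return sets


def promoter_state_stratify(
    genes: list[GeneModel], peaks: PeakSet, flank: int = 1000
) -> dict[str, list[str]]:
    """Split genes into promoter-"enriched" (>=1 peak overlapping TSS +/-
    ``flank``) vs "depleted"."""
    enriched, depleted = [], []
    for g in genes:
        t = g.tss
        win = GenomicInterval(g.chrom, max(t - flank, 0), t + flank + 1)
        if any(p.interval.overlap_len(win) > 0 for p in peaks):
            enriched.append(g.gene_id)
        else:
            depleted.append(g.gene_id)
    return {"enriched": enriched, "depleted": depleted}


def _gene_distance(site: GenomicInterval, gene: GeneModel) -> float:
    if site.chrom != gene.chrom:
        return math.inf
    if site.overlap_len(gene.body) > 0:
        return 0
    if site.end <= gene.body.start:
        return gene.body.start - site.end + 1
    return site.start - gene.body.end + 1


def nearest_gene_within(
    sites: list[GenomicInterval], genes: list[GeneModel], max_dist: int = 10000
) -> list[str | None]:
    """Per site, the nearest gene body within ``max_dist`` bp (0 if
    overlapping); ties resolved to the lexicographically smaller gene_id."""
    out: list[str | None] = []
    for site in sites:
        best: tuple[float, str] | None = None
        for g in genes:
            d = _gene_distance(site, g)
            if d <= max_dist and (best is None or (d, g.gene_id) < best):
                best = (d, g.gene_id)
        out.append(best[1] if best else None)
    return out


def consensus_de_sets(
    tables: dict[str, pd.DataFrame],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Consensus up/down gene sets across differential-expression tables.

    Per table, up = genes with log2FC >= log2(fc_threshold) and adjusted
    p <= alpha; down analogously with negative fold changes. The consensus
    sets are the intersections across all tables, so a gene moving in
    opposite directions in two tables lands in neither.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 tables for a consensus")
    lfc = math.log2(fc_threshold)
    ups, downs = [], []
    for name, df in tables.items():
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene {dup!r} in table {name!r}")
        sig = df["adj_p"] <= alpha
        ups.append(set(df.loc[sig & (df["log2fc"] >= lfc), "gene"]))
        downs.append(set(df.loc[sig & (df["log2fc"] <= -lfc), "gene"]))
    return set.intersection(*ups), set.intersection(*downs)


def ordered_matrix(matrix: pd.DataFrame, reference_column: str | None = None) -> pd.DataFrame:
    """Row-ordered matrix export for heatmap-style presentation (rows ranked
    descending by a designated reference column)."""
    if reference_column is None:
        return matrix
    return matrix.sort_values(reference_column, ascending=False, kind="mergesort")
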