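"""Fixed-width genome windows: counting, depth normalization, input subtraction.

The quantification model: fragments are binned into a fixed 200 bp grid by
fragment midpoint, each track is scaled to a common library size
(reads-per-million by default), and background is removed by subtracting the
matched sheared-input track window-by-window, floored at zero. A window is
"enriched" when any positive signal survives input subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import ChromSizes, FragmentSet, GenomicInterval, ParseError


@dataclass(frozen=True)
class WindowGrid:
    """Shared fixed-width window grid over a genome.

    Window ``i`` on a chromosome spans ``[i*w, min((i+1)*w, length))``; the
    last window may be shorter than ``w`` and is kept at native width.
    """

    sizes: ChromSizes
    window_size: int = 200

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    def n_windows(self, chrom: str) -> int:
        return -(-self.sizes[chrom] // self.window_size)

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    def window_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        w = self.window_size
        return i * w, min((i + 1) * w, self.sizes[chrom])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, WindowGrid)
            and self.window_size == other.window_size
            and dict(self.sizes) == dict(other.sizes)
        )


@dataclass
class WindowTrack:
    """Per-window scores on a :class:`WindowGrid` plus the library size."""

    grid: WindowGrid
    scores: dict[str, np.ndarray]
    library_total: int

    def __post_init__(self) -> None:
        for chrom in self.grid.chroms:
            n = self.grid.n_windows(chrom)
            arr = np.asarray(self.scores.get(chrom, np.zeros(n)), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{chrom}: expected {n} window scores, got {arr.shape}")
            self.scores[chrom] = arr

    def total_score(self) -> float:
        return float(sum(a.sum() for a in self.scores.values()))

    def copy(self) -> "WindowTrack":
        return WindowTrack(self.grid, {c: a.copy() for c, a in self.scores.items()}, self.library_total)


def count_fragments(grid: WindowGrid, frags: FragmentSet) -> WindowTrack:
    """Count fragments into windows by midpoint assignment.

    Each fragment contributes exactly 1 to the window containing
    ``floor((start+end)/2)``, so window counts sum to ``total_mapped``.
    """
    w = grid.window_size
    mids: dict[str, list[int]] = {c: [] for c in grid.chroms}
    for frag in frags:
        if frag.chrom not in mids:
            raise ValueError(f"fragment on chromosome {frag.chrom!r} absent from grid")
        if frag.end > grid.sizes[frag.chrom]:
            raise ValueError(f"fragment {frag} beyond chromosome end")
        mids[frag.chrom].append(frag.midpoint // w)
    scores = {
        c: np.bincount(np.asarray(idx, dtype=int), minlength=grid.n_windows(c)).astype(float)
        for c, idx in mids.items()
    }
    return WindowTrack(grid, scores, frags.total_mapped)


def normalize_total(track: WindowTrack, scale: float = 1e6) -> WindowTrack:
    """Scale scores to a common library size: score * scale / library_total."""
    if track.library_total <= 0:
        raise ValueError("library_total must be > 0 for normalization")
    factor = scale / track.library_total
    return WindowTrack(
        track.grid, {c: a * factor for c, a in track.scores.items()}, track.library_total
    )


def subtract_input(signal: WindowTrack, background: WindowTrack) -> WindowTrack:
    """Subtract the matched input track window-by-window, floored at zero."""
    if signal.grid != background.grid:
        raise ValueError("signal and input tracks are on different grids")
    scores = {
        c: np.maximum(signal.scores[c] - background.scores[c], 0.0) for c in signal.scores
    }
    return WindowTrack(signal.grid, scores, signal.library_total)


def enriched_windows(track: WindowTrack) -> set[tuple[str, int]]:
    """Windows with signal above background: score > 0 on a subtracted track."""
    out: set[tuple[str, int]] = set()
    for chrom, arr in track.scores.items():
        for i in np.nonzero(arr > 0)[0]:
            out.add((chrom, int(i)))
    return out


def write_track(track: WindowTrack, path: str | Path) -> None:
    """Write a track as bedGraph; scores rendered to 6 decimal places."""
    with open(path, "w") as fh:
        fh.write(f"# library_total={track.library_total} window_size={track.grid.window_size}\n")
        for chrom in track.grid.chroms:
            arr = track.scores[chrom]
            for i in range(arr.shape[0]):
                start, end = track.grid.window_bounds(chrom, i)
                fh.write(f"{chrom}\t{start}\t{end}\t{arr[i]:.6f}\n")


def read_track(path: str | Path, grid: WindowGrid, library_total: int | None = None) -> WindowTrack:
    """Read a bedGraph written by :func:`write_track` back onto ``grid``."""
    scores = {c: np.zeros(grid.n_windows(c)) for c in grid.chroms}
    total = library_total
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("library_total=") and total is None:
                        total = int(tok.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{i}: bedGraph requires 4 columns")
            chrom, start, _, score = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in scores:
                raise ParseError(f"{path}:{i}: chromosome {chrom!r} absent from grid")
            scores[chrom][start // grid.window_size] = score
    return WindowTrack(grid, scores, total if total is not None else 0)
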