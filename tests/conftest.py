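import numpy as np
import pytest

from epiwindow import ChromSizes, FragmentSet, GeneModel, GenomicInterval, WindowGrid, WindowTrack


@pytest.fixture
def small_sizes():
    return ChromSizes({"chr1": 10_000, "chr2": 4_000})


@pytest.fixture
def small_grid(small_sizes):
    return WindowGrid(small_sizes, 200)


def make_track(grid: WindowGrid, values: dict[str, list[float]], total: int = 1000) -> WindowTrack:
    scores = {}
    for chrom in grid.chroms:
        arr = np.zeros(grid.n_windows(chrom))
        vals = values.get(chrom, [])
        arr[: len(vals)] = vals
        scores[chrom] = arr
    return WindowTrack(grid, scores, total)


def random_track(grid: WindowGrid, rng: np.random.Generator, sparsity: float = 0.5) -> WindowTrack:
    scores = {}
    for chrom in grid.chroms:
        n = grid.n_windows(chrom)
        arr = rng.random(n) * 10
        arr[rng.random(n) < sparsity] = 0.0
        scores[chrom] = arr
    return WindowTrack(grid, scores, 1000)


def simple_gene(gene_id="g1", chrom="chr1", start=1000, end=3000, strand="+", exons=None):
    body = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exons = [GenomicInterval(chrom, start, start + 200, strand),
                 GenomicInterval(chrom, end - 200, end, strand)]
    return GeneModel(gene_id, body, exons)
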