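"""Synthetic pipeline inputs with planted ground truth.

Every generator is deterministic for a fixed seed and returns its truth
(planted enriched regions, differential genes, planted DigiWest effects)
alongside the data, so each downstream stage can be scored against what was
planted.

The fragment model mirrors sonicated MeDIP material: fragment lengths on a
bounded range (default 150-700 bp) with a configured mean (default 300 bp),
drawn from a truncated exponential whose scale is solved numerically to hit
the mean. Input fragments are uniform over the genome; IP fragments are
drawn by rejection against a piecewise-constant midpoint density that is
``enrichment_fold`` times higher inside each planted region.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import ChromSizes, FragmentSet, GeneModel, GenomicInterval
from .digiwest import N_FRACTIONS, FractionMatrix
from .methylation import CloneMatrix
from .repeats import RepeatAnnotation, RepeatRecord

#: small catalog of mouse retrotransposon subfamilies used for labelling
REPEAT_CATALOG = [
    ("IAPEz-int", "ERVK", "LTR"),
    ("IAPLTR1::IAPEz-int", "ERVK", "LTR"),
    ("MTA_Mm", "ERVL-MaLR", "LTR"),
    ("L1Md_A", "L1", "LINE"),
    ("L1Md_T", "L1", "LINE"),
    ("B1_Mus1", "Alu", "SINE"),
    ("B2_Mm2", "B2", "SINE"),
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: ChromSizes = field(default_factory=lambda: ChromSizes({"chr1": 1_000_000}))
    n_genes: int = 40
    n_repeats: int = 60
    n_osn_sites: int = 20
    planted_regions: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    frag_len_min: int = 150
    frag_len_max: int = 700
    frag_len_mean: float = 300.0
    depth_ip: int = 100_000
    depth_input: int = 100_000
    # bisulfite clone matrices
    n_clones: int = 24
    n_cpgs: int = 20
    clone_p_meth: dict = field(default_factory=lambda: {"serum": 0.8, "2i": 0.2})
    missing_rate: float = 0.05
    # expression tables
    n_de_up: int = 5
    n_de_down: int = 5
    de_log2fc: float = 3.0
    expr_sigma: float = 0.25
    n_replicates: int = 3
    epitypes: tuple = ("J1", "TKO", "3B3l")
    # DigiWest design
    treatments: tuple = ("serum", "2i")
    celltypes: tuple = ("J1", "TKO", "3B3l")
    n_per_cell: int = 2
    n_analytes: int = 20
    digiwest_noise_sd: float = 0.1  # sigma of multiplicative log-normal noise
    digiwest_effects_sd: dict = field(default_factory=dict)  # analyte -> (treat_sd, cell_sd)

    def __post_init__(self) -> None:
        if not (0 < self.frag_len_min < self.frag_len_max):
            raise ConfigError("fragment length bounds must satisfy 0 < min < max")
        if not (self.frag_len_min < self.frag_len_mean < self.frag_len_max):
            raise ConfigError("fragment mean must lie strictly inside [min, max]")
        for p in (*self.clone_p_meth.values(), self.missing_rate):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for iv, fold in self.planted_regions:
            if iv.chrom not in self.chrom_lengths or iv.end > self.chrom_lengths[iv.chrom]:
                raise ConfigError(f"planted region {iv} outside genome")
            if fold <= 0:
                raise ConfigError("enrichment fold must be > 0")


# ---------------------------------------------------------------------------
# genome features

def simulate_genome(
    config: SimConfig,
) -> tuple[ChromSizes, list[GeneModel], RepeatAnnotation, list[GenomicInterval]]:
    """Place non-overlapping stranded multi-exon genes, labelled repeat
    intervals, and OSN-style TF binding sites."""
    if config.n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    rng = np.random.default_rng(config.seed)
    sizes = config.chrom_lengths
    chroms = list(sizes)
    total = sum(sizes.values())
    # allocate gene counts per chromosome proportional to length
    genes: list[GeneModel] = []
    per_chrom = _proportional_counts(config.n_genes, [sizes[c] for c in chroms])
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = sizes[chrom] // n_here
        if slot < 3000:
            raise ConfigError(f"{chrom} too short to host {n_here} genes")
        for k in range(n_here):
            slot_start = k * slot
            length = int(rng.integers(2000, min(10000, slot - 500)))
            start = slot_start + int(rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + length, strand)
            genes.append(GeneModel(f"gene{gid:04d}", body, _random_exons(rng, body)))
            gid += 1
    repeats = _simulate_repeats(rng, sizes, config.n_repeats)
    osn = _random_intervals(rng, sizes, config.n_osn_sites, 200, 500)
    return sizes, genes, repeats, osn


def _proportional_counts(n: int, weights: Sequence[int]) -> list[int]:
    total = sum(weights)
    counts = [int(n * w / total) for w in weights]
    i = 0
    while sum(counts) < n:
        counts[i % len(counts)] += 1
        i += 1
    return counts


def _random_exons(rng: np.random.Generator, body: GenomicInterval) -> list[GenomicInterval]:
    n_exons = int(rng.integers(1, 6))
    length = len(body)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 1, replace=False)) if 2 * n_exons - 1 < length else np.array([])
    if cuts.size < 2 * n_exons - 1:
        return [GenomicInterval(body.chrom, body.start, body.end, body.strand)]
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for j in range(0, len(bounds) - 1, 2):
        a, b = int(bounds[j]), int(bounds[j + 1])
        if b > a:
            exons.append(GenomicInterval(body.chrom, body.start + a, body.start + b, body.strand))
    return exons


def _random_intervals(
    rng: np.random.Generator, sizes: ChromSizes, n: int, min_len: int, max_len: int
) -> list[GenomicInterval]:
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, sizes[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def _simulate_repeats(rng: np.random.Generator, sizes: ChromSizes, n: int) -> RepeatAnnotation:
    records = []
    for iv in _random_intervals(rng, sizes, n, 300, 6000):
        sub, fam, cls_ = REPEAT_CATALOG[int(rng.integers(len(REPEAT_CATALOG)))]
        records.append(RepeatRecord(iv, sub, fam, cls_))
    return RepeatAnnotation(records)


# ---------------------------------------------------------------------------
# fragments

def _fragment_length_sampler(config: SimConfig):
    """Truncated exponential on [min, max] with scale solved so the mean
    matches; falls back to uniform when the mean is the interval midpoint and
    mirrors the distribution when the mean is above it."""
    lo, hi, mean = config.frag_len_min, config.frag_len_max, config.frag_len_mean
    span = hi - lo
    mid = (lo + hi) / 2.0
    if math.isclose(mean, mid, rel_tol=1e-9):
        return lambda rng, n: rng.uniform(lo, hi, size=n)
    mirrored = mean > mid
    target = (mean - lo) if not mirrored else (hi - mean)

    def trunc_mean(scale: float) -> float:
        b = span / scale
        return scale * (1.0 - b * math.exp(-b) / (1.0 - math.exp(-b)))

    scale = optimize.brentq(lambda s: trunc_mean(s) - target, 1e-3 * span, 1e4 * span)
    b = span / scale

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        x = stats.truncexpon.rvs(b, scale=scale, size=n, random_state=rng)
        return (lo + x) if not mirrored else (hi - x)

    return draw


def _draw_uniform_midpoints(
    rng: np.random.Generator, sizes: ChromSizes, n: int
) -> tuple[np.ndarray, np.ndarray]:
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    mids = (rng.random(n) * lengths[chrom_idx]).astype(int)
    return chrom_idx, mids


def _fold_at(config: SimConfig, chroms: list[str], chrom_idx: np.ndarray, mids: np.ndarray) -> np.ndarray:
    fold = np.ones(mids.shape[0])
    for iv, f in config.planted_regions:
        ci = chroms.index(iv.chrom)
        inside = (chrom_idx == ci) & (mids >= iv.start) & (mids < iv.end)
        fold[inside] = f
    return fold


def simulate_fragments(
    config: SimConfig, planted: list[tuple[GenomicInterval, float]] | None = None
) -> tuple[FragmentSet, FragmentSet]:
    """Draw (IP, input) fragment sets; IP midpoint density is multiplied by
    the enrichment fold inside each planted region (rejection sampling)."""
    if config.depth_ip <= 0 or config.depth_input <= 0:
        raise ConfigError("depths must be > 0")
    cfg = config
    if planted is not None:
        cfg = SimConfig(**{**config.__dict__, "planted_regions": planted})
    rng = np.random.default_rng(cfg.seed + 1)
    sampler = _fragment_length_sampler(cfg)
    chroms = list(cfg.chrom_lengths)

    def build(chrom_idx: np.ndarray, mids: np.ndarray) -> FragmentSet:
        lengths = np.maximum(sampler(rng, mids.shape[0]).astype(int), 1)
        frags = []
        for ci, mid, ln in zip(chrom_idx, mids, lengths):
            chrom = chroms[ci]
            L = cfg.chrom_lengths[chrom]
            start = max(int(mid) - int(ln) // 2, 0)
            end = min(start + int(ln), L)
            start = max(min(start, end - 1), 0)
            frags.append(GenomicInterval(chrom, start, end))
        return FragmentSet(frags)

    # input: uniform midpoints
    in_idx, in_mids = _draw_uniform_midpoints(rng, cfg.chrom_lengths, cfg.depth_input)
    input_set = build(in_idx, in_mids)

    # IP: rejection against the piecewise-constant enrichment density
    max_fold = max([f for _, f in cfg.planted_regions], default=1.0)
    ip_idx = np.empty(0, dtype=int)
    ip_mids = np.empty(0, dtype=int)
    while ip_mids.shape[0] < cfg.depth_ip:
        batch = max(2 * (cfg.depth_ip - ip_mids.shape[0]), 1000)
        ci, mids = _draw_uniform_midpoints(rng, cfg.chrom_lengths, batch)
        accept = rng.random(batch) < _fold_at(cfg, chroms, ci, mids) / max_fold
        ip_idx = np.concatenate([ip_idx, ci[accept]])
        ip_mids = np.concatenate([ip_mids, mids[accept]])
    ip_set = build(ip_idx[: cfg.depth_ip], ip_mids[: cfg.depth_ip])
    return ip_set, input_set


def place_planted_regions(
    config: SimConfig, n_regions: int, region_len: int = 2000, fold: float = 10.0
) -> list[tuple[GenomicInterval, float]]:
    """Evenly spaced, non-overlapping planted enriched regions."""
    rng = np.random.default_rng(config.seed + 2)
    sizes = config.chrom_lengths
    chroms = list(sizes)
    per_chrom = _proportional_counts(n_regions, [sizes[c] for c in chroms])
    out = []
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = sizes[chrom] // n_here
        if slot <= region_len:
            raise ConfigError(f"{chrom} too short for {n_here} regions of {region_len} bp")
        for k in range(n_here):
            start = k * slot + int(rng.integers(0, slot - region_len))
            out.append((GenomicInterval(chrom, start, start + region_len), fold))
    return out


# ---------------------------------------------------------------------------
# clone matrices, expression tables, DigiWest fraction profiles

def simulate_clone_matrix(config: SimConfig, condition: str = "serum") -> CloneMatrix:
    """Bernoulli(p_meth) CpG calls with cells missing at ``missing_rate``."""
    p = config.clone_p_meth[condition]
    rng = np.random.default_rng(config.seed + 3 + zlib.crc32(condition.encode()) % 100000)
    calls = (rng.random((config.n_clones, config.n_cpgs)) < p).astype(float)
    missing = rng.random(calls.shape) < config.missing_rate
    # keep the matrix valid: never blank out every cell
    if missing.all():
        missing.flat[0] = False
    calls[missing] = np.nan
    return CloneMatrix(f"{condition}_amplicon", calls)


def simulate_expression(config: SimConfig) -> tuple[dict[str, pd.DataFrame], dict[str, set]]:
    """Per-epitype differential-expression tables (gene, log2fc, adj_p).

    Log2 expression is Normal per gene (i.e. log-normal expression) with a
    planted 2i shift of +/- ``de_log2fc`` for the consensus up/down genes in
    every epitype. Fold changes and Welch-t adjusted p-values (BH) are
    computed from ``n_replicates`` per condition.
    """
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(config.seed + 4)
    gene_ids = [f"gene{j:04d}" for j in range(config.n_genes)]
    n_up, n_down = config.n_de_up, config.n_de_down
    if n_up + n_down > config.n_genes:
        raise ConfigError("more planted DE genes than genes")
    up = set(gene_ids[:n_up])
    down = set(gene_ids[n_up : n_up + n_down])
    base = rng.normal(6.0, 2.0, size=config.n_genes)
    tables = {}
    for epi in config.epitypes:
        delta = np.zeros(config.n_genes)
        delta[:n_up] = config.de_log2fc
        delta[n_up : n_up + n_down] = -config.de_log2fc
        serum = rng.normal(base[:, None], config.expr_sigma, size=(config.n_genes, config.n_replicates))
        two_i = rng.normal(
            (base + delta)[:, None], config.expr_sigma, size=(config.n_genes, config.n_replicates)
        )
        log2fc = two_i.mean(axis=1) - serum.mean(axis=1)
        p = stats.ttest_ind(two_i, serum, axis=1, equal_var=False).pvalue
        adj_p = multipletests(p, method="fdr_bh")[1]
        tables[epi] = pd.DataFrame({"gene": gene_ids, "log2fc": log2fc, "adj_p": adj_p})
    return tables, {"up": up, "down": down}


def simulate_fraction_matrix(config: SimConfig) -> tuple[FractionMatrix, dict]:
    """96-fraction analyte profiles with factorial (treatment x celltype)
    effects.

    Each analyte is a Gaussian band at an analyte-specific fraction. A
    sample's band amplitude carries multiplicative log-normal noise
    (sigma = ``digiwest_noise_sd`` on the natural log) shared across the 96
    fractions, so band sums are exactly log-normal. Planted effects are
    given per analyte in pooled-SD units of the downstream log2
    actin-normalized response and converted to log2 fold changes internally
    (one unit = noise_sd * sqrt(2) / ln 2, the actin normalization doubling
    the variance). A "beta_actin" analyte with no planted effect is always
    included.
    """
    rng = np.random.default_rng(config.seed + 5)
    samples, treat, cell = [], [], []
    for t in config.treatments:
        for c in config.celltypes:
            for r in range(config.n_per_cell):
                samples.append(f"{c}_{t}_{r + 1}")
                treat.append(t)
                cell.append(c)
    design = pd.DataFrame({"treatment": treat, "celltype": cell}, index=samples)
    analytes = ["beta_actin"] + [f"analyte{i:03d}" for i in range(config.n_analytes)]
    sd_to_log2 = config.digiwest_noise_sd * math.sqrt(2.0) / math.log(2.0)
    cell_code = {c: i - (len(config.celltypes) - 1) / 2.0 for i, c in enumerate(config.celltypes)}
    fracs = np.arange(1, N_FRACTIONS + 1)
    arr = np.zeros((len(analytes), len(samples), N_FRACTIONS))
    truth = {"effects_sd": dict(config.digiwest_effects_sd), "sd_to_log2": sd_to_log2, "band": {}}
    for i, analyte in enumerate(analytes):
        center = float(rng.uniform(10, 86))
        width = float(rng.uniform(1.5, 3.0))
        base_amp = float(rng.uniform(500, 5000))
        truth["band"][analyte] = (center, width)
        band = np.exp(-0.5 * ((fracs - center) / width) ** 2)
        t_sd, c_sd = config.digiwest_effects_sd.get(analyte, (0.0, 0.0))
        for j, s in enumerate(samples):
            log2_shift = 0.0
            if design.loc[s, "treatment"] == config.treatments[1]:
                log2_shift += t_sd * sd_to_log2
            log2_shift += c_sd * sd_to_log2 * cell_code[design.loc[s, "celltype"]]
            noise = math.exp(rng.normal(0.0, config.digiwest_noise_sd))
            arr[i, j] = base_amp * (2.0 ** log2_shift) * noise * band
    return FractionMatrix(arr, analytes, samples, design), truth


def default_bands(truth: dict, n_sigma: float = 3.0) -> dict[str, tuple[int, int]]:
    """Band windows of +/- ``n_sigma`` band widths around each planted center."""
    bands = {}
    for analyte, (center, width) in truth["band"].items():
        lo = max(1, int(math.floor(center - n_sigma * width)))
        hi = min(N_FRACTIONS, int(math.ceil(center + n_sigma * width)))
        bands[analyte] = (lo, hi)
    return bands
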