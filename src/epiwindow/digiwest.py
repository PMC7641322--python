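"""High-content western (DigiWest) analytics.

Each sample is resolved into 96 molecular-weight fractions read on a Luminex
instrument. This module covers: 0-1 scaling of background-subtracted
fraction data per antibody, reconstruction of blot-like images with Gaussian
diffusion, band-window quantification to per-analyte values, beta-actin
normalization with log2 transform, a permutation two-factor ANOVA (factor 1:
2i treatment; factor 2: cell type), and Euclidean average-linkage clustering
of significant analytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.ndimage import gaussian_filter

N_FRACTIONS = 96


@dataclass
class FractionMatrix:
    """Analyte x sample x 96-fraction intensities plus the sample design."""

    intensities: np.ndarray  # (n_analytes, n_samples, 96), >= 0
    analytes: list[str]
    samples: list[str]
    design: pd.DataFrame  # index: samples; columns: treatment, celltype

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n_a, n_s, n_f = self.intensities.shape
        if n_f != N_FRACTIONS:
            raise ValueError(f"expected {N_FRACTIONS} fractions, got {n_f}")
        if (n_a, n_s) != (len(self.analytes), len(self.samples)):
            raise ValueError("intensity array does not match analyte/sample labels")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be background-subtracted and >= 0")
        if list(self.design.index) != list(self.samples):
            self.design = self.design.loc[self.samples]

    def analyte_index(self, name: str) -> int:
        return self.analytes.index(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, analyte in enumerate(self.analytes):
            for j, sample in enumerate(self.samples):
                rows.append([analyte, sample, *self.intensities[i, j]])
        cols = ["analyte", "sample"] + [f"fraction_{k}" for k in range(1, N_FRACTIONS + 1)]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frames(cls, fractions: pd.DataFrame, design: pd.DataFrame) -> "FractionMatrix":
        analytes = list(dict.fromkeys(fractions["analyte"]))
        samples = list(dict.fromkeys(fractions["sample"]))
        frac_cols = [f"fraction_{k}" for k in range(1, N_FRACTIONS + 1)]
        arr = np.zeros((len(analytes), len(samples), N_FRACTIONS))
        ai = {a: i for i, a in enumerate(analytes)}
        si = {s: j for j, s in enumerate(samples)}
        for _, row in fractions.iterrows():
            arr[ai[row["analyte"]], si[row["sample"]]] = row[frac_cols].to_numpy(float)
        return cls(arr, analytes, samples, design.set_index("sample") if "sample" in design else design)


def scale_blot(f: FractionMatrix, analyte: str) -> np.ndarray:
    """Scale one antibody's fraction data to [0, 1] by its global maximum
    (the highest measured signal across all samples and fractions is 1)."""
    block = f.intensities[f.analyte_index(analyte)]
    peak = block.max()
    if peak <= 0:
        raise ValueError(f"analyte {analyte!r} has no signal to scale")
    return block / peak


def render_blot(scaled: np.ndarray, element_height: int = 10, lane_width: int = 20) -> np.ndarray:
    """Reconstruct a blot-like greyscale image from scaled fraction data.

    Each (fraction, sample) cell is painted as an ``element_height``-tall,
    ``lane_width``-wide block (0 = white, 1 = black; fractions run down the
    image, one lane per sample), then diffused with a Gaussian of radius half
    the element height (sigma = radius / 2, reflective padding).
    """
    if element_height < 2:
        raise ValueError("element_height must be >= 2")
    n_samples, n_fractions = scaled.shape
    img = np.repeat(np.repeat(scaled.T, element_height, axis=0), lane_width, axis=1)
    radius = element_height / 2.0
    return gaussian_filter(img, sigma=radius / 2.0, mode="reflect")


def quantify_analyte(f: FractionMatrix, bands: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-sample analyte values: sum of intensities over the analyte's band
    window (1-based inclusive fraction indices)."""
    rows = {}
    for analyte, (lo, hi) in bands.items():
        if not (1 <= lo <= hi <= N_FRACTIONS):
            raise ValueError(f"band window for {analyte!r} must lie within 1..{N_FRACTIONS}")
        block = f.intensities[f.analyte_index(analyte)]
        rows[analyte] = block[:, lo - 1 : hi].sum(axis=1)
    return pd.DataFrame(rows, index=f.samples).T


def normalize_to_actin(
    values: pd.DataFrame, actin: pd.Series, pseudo_floor: float | None = None
) -> pd.DataFrame:
    """log2(value / beta-actin) per cell.

    Zeros are lifted to a pseudo-floor before the log (default: half the
    smallest positive value of that analyte) so the transform stays finite.
    """
    if (actin <= 0).any():
        raise ValueError("beta-actin values must be > 0 in every sample")
    out = values.astype(float).copy()
    for analyte in out.index:
        row = out.loc[analyte].to_numpy(float)
        if (row <= 0).any():
            if pseudo_floor is not None:
                floor = pseudo_floor
            else:
                pos = row[row > 0]
                if pos.size == 0:
                    raise ValueError(f"analyte {analyte!r} is zero in every sample")
                floor = pos.min() / 2.0
            row = np.maximum(row, floor)
        out.loc[analyte] = np.log2(row / actin.loc[out.columns].to_numpy(float))
    return out


def _residual_maker(X: np.ndarray) -> np.ndarray:
    hat = X @ np.linalg.pinv(X)
    return np.eye(X.shape[0]) - hat


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels, drop_first=True).to_numpy(float)


def permutation_anova2(
    values: pd.DataFrame,
    factor_a: pd.Series,
    factor_b: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation two-factor ANOVA per analyte.

    Observed F statistics come from the standard two-way fixed-effects
    decomposition (Type-II sums of squares; identical to Type I/III on the
    balanced design). The null distribution permutes sample labels jointly
    ``n_perm`` times, the same permutations shared across analytes, and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the smallest attainable
    p is 1/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation p resolution is coarse", stacklevel=2)
    samples = list(values.columns)
    fa = factor_a.loc[samples]
    fb = factor_b.loc[samples]
    cells = pd.crosstab(fa, fb)
    if (cells.to_numpy() == 0).any():
        raise ValueError("every treatment x celltype design cell needs >= 1 observation")
    n = len(samples)
    a_levels, b_levels = cells.shape
    df_a, df_b = a_levels - 1, b_levels - 1
    df_ab = df_a * df_b
    df_e = n - a_levels * b_levels
    if df_e <= 0:
        raise ValueError("no residual degrees of freedom (need replication within cells)")

    one = np.ones((n, 1))
    da, db = _dummies(fa), _dummies(fb)
    dab = np.concatenate(
        [da[:, [i]] * db[:, [j]] for i in range(da.shape[1]) for j in range(db.shape[1])], axis=1
    )
    R = {
        "a": _residual_maker(np.hstack([one, da])),
        "b": _residual_maker(np.hstack([one, db])),
        "ab": _residual_maker(np.hstack([one, da, db])),
        "full": _residual_maker(np.hstack([one, da, db, dab])),
    }

    def f_stats(Y: np.ndarray) -> np.ndarray:
        rss = {k: np.einsum("an,nm,am->a", Y, M, Y) for k, M in R.items()}
        ss_a = rss["b"] - rss["ab"]
        ss_b = rss["a"] - rss["ab"]
        ss_ab = rss["ab"] - rss["full"]
        ms_e = rss["full"] / df_e
        scale = np.abs(Y).max(axis=1) ** 2 + 1.0
        eps = 1e-12 * scale
        out = []
        for ss, df in ((ss_a, df_a), (ss_b, df_b), (ss_ab, df_ab)):
            ms = np.maximum(ss, 0.0) / df
            f = np.where(ms_e > eps, ms / np.maximum(ms_e, 1e-300), np.where(ms > eps, np.inf, 0.0))
            out.append(f)
        return np.stack(out)  # (3, n_analytes)

    Y = values.to_numpy(float)
    f_obs = f_stats(Y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(f_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += f_stats(Y[:, perm]) >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "F_A": f_obs[0],
            "F_B": f_obs[1],
            "F_AB": f_obs[2],
            "p_A": pvals[0],
            "p_B": pvals[1],
            "p_AB": pvals[2],
        },
        index=values.index,
    )


def cluster_significant(
    values: pd.DataFrame, pvals: pd.DataFrame, alpha: float = 0.005
) -> tuple[list[str], np.ndarray | None]:
    """Euclidean average-linkage clustering of analytes significant in any
    factor (min of the three permutation p-values <= alpha).

    Returns the leaf-ordered analyte list and the linkage matrix; with fewer
    than two significant analytes the list is returned without a tree.
    """
    pmin = pvals[["p_A", "p_B", "p_AB"]].min(axis=1)
    significant = sorted(pmin.index[pmin <= alpha])
    if len(significant) < 2:
        warnings.warn("fewer than 2 significant analytes; no clustering performed", stacklevel=2)
        return significant, None
    mat = values.loc[significant].to_numpy(float)
    Z = linkage(mat, method="average", metric="euclidean")
    order = [significant[i] for i in leaves_list(Z)]
    return order, Z
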