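"""Bisulfite clone-matrix methylation quantification and global 5mC by HPLC.

A bisulfite amplicon is summarized as a clone x CpG call matrix with ternary
entries (methylated / unmethylated / missing). Percent methylation is the
methylated fraction of non-missing calls; two conditions are compared by a
two-tailed Mann-Whitney U test on per-clone methylation levels (clones are
the independent sequencing units). Global 5mC percent comes from HPLC peak
areas at the dCMP (276 nm) and 5mdCMP (282 nm) extinction maxima, converted
to molar amounts with the respective extinction coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

METH, UNMETH, MISSING = 1.0, 0.0, np.nan

#: molar extinction coefficients (L mol^-1 cm^-1) at the detection maxima
EPS_DCMP = 8.86e3  # dCMP at 276 nm
EPS_5MDCMP = 9.0e3  # 5mdCMP at 282 nm


@dataclass
class CloneMatrix:
    """Clone x CpG calls: 1 = methylated, 0 = unmethylated, NaN = missing."""

    amplicon_id: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2 or 0 in self.calls.shape:
            raise ValueError("calls must be a non-empty clone x CpG matrix")
        valid = ~np.isnan(self.calls)
        if not valid.any():
            raise ValueError("matrix has no non-missing calls")
        vals = self.calls[valid]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("non-missing calls must be 0 or 1")

    @classmethod
    def read_tsv(cls, path: str | Path, amplicon_id: str | None = None) -> "CloneMatrix":
        df = pd.read_csv(path, sep="\t", header=None, na_values=["NA"])
        return cls(amplicon_id or Path(path).stem, df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.calls).to_csv(
            path, sep="\t", header=False, index=False, na_rep="NA", float_format="%.0f"
        )


def percent_methylation(m: CloneMatrix) -> float:
    """100 x methylated / (methylated + unmethylated), missing cells excluded."""
    valid = ~np.isnan(m.calls)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no non-missing calls")
    return 100.0 * float(np.nansum(m.calls)) / n


def clone_methylation_levels(m: CloneMatrix, axis: str = "clone") -> np.ndarray:
    """Fraction methylated per clone (rows) or per CpG column, over
    non-missing calls; all-missing rows/columns are dropped with a warning."""
    calls = m.calls if axis == "clone" else m.calls.T
    if axis not in {"clone", "cpg"}:
        raise ValueError("axis must be 'clone' or 'cpg'")
    counts = (~np.isnan(calls)).sum(axis=1)
    if (counts == 0).any():
        warnings.warn(f"dropping {(counts == 0).sum()} all-missing {axis}(s)", stacklevel=2)
    keep = counts > 0
    with np.errstate(invalid="ignore"):
        return np.nansum(calls[keep], axis=1) / counts[keep]


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact p by enumeration when the combined sample size is <= 20 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U for sample a, two-tailed p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class HplcAreas:
    """Peak areas under the dCMP (276 nm) and 5mdCMP (282 nm) peaks."""

    a_dcmp: float
    a_5mdcmp: float
    eps_dcmp: float = EPS_DCMP
    eps_5mdcmp: float = EPS_5MDCMP

    def __post_init__(self) -> None:
        if self.a_dcmp < 0 or self.a_5mdcmp < 0:
            raise ValueError("areas must be >= 0")
        if self.eps_dcmp <= 0 or self.eps_5mdcmp <= 0:
            raise ValueError("extinction coefficients must be > 0")


def hplc_percent_5mc(h: HplcAreas) -> float:
    """Percent 5mC of total cytosine from extinction-corrected peak areas:
    100 * (a_5mdCMP/eps_5mdCMP) / (a_dCMP/eps_dCMP + a_5mdCMP/eps_5mdCMP)."""
    if h.a_dcmp + h.a_5mdcmp == 0:
        raise ValueError("both peak areas are zero")
    n_c = h.a_dcmp / h.eps_dcmp
    n_5mc = h.a_5mdcmp / h.eps_5mdcmp
    return 100.0 * n_5mc / (n_c + n_5mc)


def compare_conditions(a: CloneMatrix, b: CloneMatrix) -> dict[str, float]:
    """Percent methylation per condition plus the two-tailed MWU comparison
    of per-clone methylation levels."""
    u, p = mann_whitney_u(clone_methylation_levels(a), clone_methylation_levels(b))
    return {
        "percent_a": percent_methylation(a),
        "percent_b": percent_methylation(b),
        "U": u,
        "p": p,
    }
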