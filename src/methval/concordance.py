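"""Gold-standard comparison of array against WGBS methylation levels.

Loci are paired through an explicit probe↔site mapping, filtered to a
coverage window (low-coverage sites have poor resolution because the WGBS
level is a read fraction; very high coverage flags technical artifacts),
then compared two ways:

* accuracy — Pearson product-moment correlation of the paired levels;
* reportable range — ordinary least squares of the WGBS level y on the
  array level x,  y = a + b·x + e,  solved for the measurement values at
  which the fitted truth reaches 0 and 1:

      R_low  = max(0, −a/b),      R_high = min(1, (1 − a)/b).

Per-sample ranges are aggregated across samples as the largest overlapping
range: [max of lows, min of highs].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .methio import WGBSSiteTable

__all__ = [
    "filter_comparable_loci",
    "accuracy_correlation",
    "fit_reportable_range",
    "aggregate_reportable_range",
    "LinearFit",
]

MIN_COVERAGE = 30
MAX_COVERAGE = 100


@dataclass
class LinearFit:
    """OLS fit of WGBS on array levels with reportable-range cut-offs."""

    a: float          # intercept, level units
    b: float          # slope
    adj_r2: float
    n: int
    r_low: float
    r_high: float


def filter_comparable_loci(wgbs: WGBSSiteTable, array: pd.Series,
                           mapping: pd.DataFrame,
                           min_cov: int = MIN_COVERAGE,
                           max_cov: int = MAX_COVERAGE) -> pd.DataFrame:
    """Pair array probes with WGBS sites and apply the coverage window.

    ``array`` is a Series of levels indexed by probe_id; ``mapping`` has
    columns probe_id, chrom, pos, strand. Sites with coverage in
    [min_cov, max_cov] (inclusive) and present on both platforms are kept.
    Returns a DataFrame with columns probe_id, x (array), y (WGBS),
    coverage.
    """
    for col in ("probe_id", "chrom", "pos", "strand"):
        if col not in mapping.columns:
            raise ValueError(f"mapping is missing column {col!r}")
    sites = wgbs.frame.set_index(["chrom", "pos", "strand"])
    keyed = mapping.set_index(["chrom", "pos", "strand"])
    joined = keyed.join(sites[["level", "coverage"]], how="inner")
    joined = joined.reset_index(drop=True)
    joined["x"] = joined["probe_id"].map(array)
    joined = joined.dropna(subset=["x"])
    kept = joined[(joined["coverage"] >= min_cov)
                  & (joined["coverage"] <= max_cov)]
    if len(kept) == 0:
        raise ValueError(
            f"no loci survive the coverage window [{min_cov}, {max_cov}]"
        )
    out = kept.rename(columns={"level": "y"})
    return out[["probe_id", "x", "y", "coverage"]].reset_index(drop=True)


def accuracy_correlation(pairs: pd.DataFrame) -> float:
    """Pearson correlation between array (x) and WGBS (y) levels."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one coordinate")
    return float(stats.pearsonr(x, y).statistic)


def fit_reportable_range(pairs: pd.DataFrame,
                         iterative: bool = False,
                         tol: float = 1e-4,
                         max_iter: int = 20) -> LinearFit:
    """OLS of WGBS on array with reportable-range cut-offs.

    With ``iterative=True`` the fit is repeated on the pairs whose array
    level lies inside the current [R_low, R_high] until the cut-offs move
    by less than ``tol`` — a trimmed variant for data whose extremes leave
    the linear regime. The default single pass reproduces the published
    cut-offs on well-behaved data.
    """
    fit = _ols_range(pairs)
    if not iterative:
        return fit
    for _ in range(max_iter):
        inside = pairs[(pairs["x"] >= fit.r_low) & (pairs["x"] <= fit.r_high)]
        new = _ols_range(inside)
        if abs(new.r_low - fit.r_low) < tol and abs(new.r_high - fit.r_high) < tol:
            return new
        fit = new
    return fit


def _ols_range(pairs: pd.DataFrame) -> LinearFit:
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs to fit")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = float(model.params[0]), float(model.params[1])
    if b <= 0:
        raise ValueError(f"fitted slope b={b:.4g} <= 0: range undefined")
    return LinearFit(
        a=a,
        b=b,
        adj_r2=float(model.rsquared_adj),
        n=int(len(x)),
        r_low=max(0.0, -a / b),
        r_high=min(1.0, (1.0 - a) / b),
    )


def aggregate_reportable_range(fits) -> tuple[float, float]:
    """Largest range covered by every per-sample fit: [max(R_low),
    min(R_high)]. ``fits`` may hold :class:`LinearFit` objects or
    (low, high) tuples."""
    lows, highs = [], []
    for f in fits:
        if isinstance(f, LinearFit):
            lows.append(f.r_low)
            highs.append(f.r_high)
        else:
            lo, hi = f
            lows.append(float(lo))
            highs.append(float(hi))
    if not lows:
        raise ValueError("no fits to aggregate")
    low, high = max(lows), min(highs)
    if low > high:
        raise ValueError(
            f"per-sample reportable ranges do not overlap "
            f"(max low {low:.4g} > min high {high:.4g})"
        )
    return (low, high)
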