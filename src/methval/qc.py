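"""Detection-p-value sensitivity QC and intensity-based specificity QC.

Detection p-values test whether a probe's total signal (M + U) exceeds
background fluorescence. Background-control probes carry single-channel
background draws in both columns; pooling those per-channel values gives
(μ̂, σ̂) of the background distribution. Under the null a probe's total is
the sum of two background draws, Normal(2μ̂, 2σ̂²), so

    p = 1 − Φ((M + U − 2μ̂) / (√2·σ̂)).

Probes with p > 0.01 are failed; samples with more than 5% failed probes
are failed.

The sample-intensity statistic is MU = log2 √(median(M)·median(U)) over
non-control probes. The specificity procedure derives the 99% normal range
of per-sample aberrant-call counts from clean replicates, labels samples
outside it failed, and learns the midpoint (max-margin) MU threshold
separating failed from passed samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methio import IntensityTable

__all__ = [
    "detection_pvalues",
    "failed_probe_mask",
    "sample_sensitivity_pass",
    "mu_statistic",
    "beta_from_intensities",
    "normal_aberrant_range",
    "learn_mu_threshold",
    "SampleQC",
]

DETECTION_P_CUTOFF = 0.01
FAILED_FRACTION_CUTOFF = 0.05


@dataclass
class SampleQC:
    """QC summary for one sample."""

    sample_id: str
    failed_probe_fraction: float
    sensitivity_pass: bool
    mu: float
    specificity_pass: bool | None = None
    aberrant_count: int | None = None


def detection_pvalues(intensities: IntensityTable) -> pd.Series:
    """Per-probe detection p-values from the background-control model."""
    controls = intensities.controls
    if len(controls) < 10:
        raise ValueError(
            f"need >= 10 background-control rows, got {len(controls)}"
        )
    pooled = np.concatenate([controls["M"].to_numpy(),
                             controls["U"].to_numpy()])
    mu_hat = float(np.mean(pooled))
    sd_hat = float(np.std(pooled, ddof=1))
    if sd_hat == 0.0:
        raise ValueError("degenerate background controls (zero spread)")
    probes = intensities.probes
    total = probes["M"].to_numpy() + probes["U"].to_numpy()
    z = (total - 2.0 * mu_hat) / (np.sqrt(2.0) * sd_hat)
    return pd.Series(stats.norm.sf(z), index=probes.index, name="detection_p")


def failed_probe_mask(pvalues: pd.Series,
                      cutoff: float = DETECTION_P_CUTOFF
                      ) -> tuple[pd.Series, float]:
    """Mask of failed probes (p strictly greater than cutoff) and the
    failed fraction."""
    if len(pvalues) == 0:
        raise ValueError("no probes")
    mask = pvalues > cutoff
    return mask, float(mask.mean())


def sample_sensitivity_pass(fraction: float,
                            cutoff: float = FAILED_FRACTION_CUTOFF) -> bool:
    """A sample passes unless strictly more than ``cutoff`` of its probes
    failed detection."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("failed fraction outside [0, 1]")
    return fraction <= cutoff


def mu_statistic(intensities: IntensityTable) -> float:
    """log2 of the geometric mean of the median M and median U intensities
    over non-control probes."""
    probes = intensities.probes
    med_m = float(probes["M"].median())
    med_u = float(probes["U"].median())
    if med_m <= 0 or med_u <= 0:
        raise ValueError(
            f"non-positive median intensity (M={med_m}, U={med_u})"
        )
    return float(np.log2(np.sqrt(med_m * med_u)))


def beta_from_intensities(intensities: IntensityTable,
                          offset: float = 100.0) -> pd.Series:
    """Methylation beta values M / (M + U + offset) for non-control probes."""
    probes = intensities.probes
    beta = probes["M"] / (probes["M"] + probes["U"] + offset)
    return beta.rename("beta")


def normal_aberrant_range(counts, level: float = 0.99) -> tuple[float, float]:
    """Normal range of aberrant-call counts from clean replicates.

    Normal-approximation interval mean ± z·sd at the given coverage level,
    floored at 0. An empirical percentile pair is meaningless at the
    handful of clean replicates typically available, hence the parametric
    form.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need >= 3 clean-replicate counts")
    z = stats.norm.ppf(0.5 + level / 2.0)
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    return (max(0.0, mean - z * sd), mean + z * sd)


def learn_mu_threshold(mu_failed, mu_passed) -> float:
    """Max-margin 1-D threshold between failed and passed MU values.

    Requires the groups to be linearly separable with every failed MU below
    every passed MU; the separator is the midpoint of the gap. Samples with
    MU below the returned threshold are labeled failed.
    """
    mu_failed = np.asarray(mu_failed, dtype=float)
    mu_passed = np.asarray(mu_passed, dtype=float)
    if mu_failed.size == 0 or mu_passed.size == 0:
        raise ValueError("both groups must be non-empty")
    hi_failed = float(mu_failed.max())
    lo_passed = float(mu_passed.min())
    if hi_failed >= lo_passed:
        overlap = (lo_passed, hi_failed)
        raise ValueError(
            f"failed and passed MU values are not separable: failed reach "
            f"{overlap[1]:.4g} while passed start at {overlap[0]:.4g}"
        )
    return (hi_failed + lo_passed) / 2.0
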