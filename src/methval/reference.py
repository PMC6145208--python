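"""Per-locus reference intervals and locus detectability.

The reference interval for a locus is the empirical 95% interval — the
[2.5th, 97.5th] percentile pair — of methylation levels across a
known-normal reference population, together with the usual order statistics
(min, quartiles, max). Quantiles use linear interpolation between order
statistics at position (n − 1)·p.

A locus is *detectable* in a direction if an aberrant call in that
direction is geometrically possible given the calling threshold ``t``:
hyper-aberrant levels must fit below 1 (``upper + t < 1``) and hypo-aberrant
levels must sit above the assay's lower reportable bound
(``lower − t > max(0, reportable_low)``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .methio import BetaMatrix

__all__ = [
    "build_reference",
    "summarize_iqr",
    "classify_detectability",
    "detectability_summary",
    "read_reference_table",
    "write_reference_table",
    "DETECTABILITY_CLASSES",
]

DETECTABILITY_CLASSES = ("both", "hyper_only", "hypo_only", "undetectable")

_COLUMNS = ["min", "q1", "median", "q3", "max", "lower", "upper", "n",
            "detectability"]


def build_reference(reference: BetaMatrix) -> pd.DataFrame:
    """Per-locus reference statistics from a reference population.

    Returns a DataFrame indexed by locus_id with columns min, q1, median,
    q3, max, lower (2.5th pct), upper (97.5th pct) and n (available-case
    count). Loci with fewer than 2 non-missing values get NaN statistics.
    The ``detectability`` column is initialised empty; fill it with
    :func:`classify_detectability`.
    """
    if len(reference.locus_ids) == 0:
        raise ValueError("empty beta matrix")
    values = reference.values
    n_avail = np.sum(~np.isnan(values), axis=1)
    out = pd.DataFrame(index=pd.Index(reference.locus_ids, name="locus_id"),
                       columns=_COLUMNS, dtype=object)
    ok = n_avail >= 2
    stats = np.full((values.shape[0], 7), np.nan)
    if ok.any():
        with np.errstate(invalid="ignore"):
            qs = np.nanquantile(
                values[ok], [0.0, 0.25, 0.5, 0.75, 1.0, 0.025, 0.975],
                axis=1, method="linear",
            )
        stats[ok] = qs.T
    for j, col in enumerate(["min", "q1", "median", "q3", "max", "lower",
                             "upper"]):
        out[col] = stats[:, j]
    out["n"] = n_avail
    out["detectability"] = pd.NA
    return out


def summarize_iqr(table: pd.DataFrame, bin_width: float = 0.005) -> dict:
    """Distribution summary of the per-locus interquartile range.

    Returns the IQR values, a histogram over [0, 1] with the given bin
    width, the mode (midpoint of the most populated bin), and the fraction
    of loci whose 95% interval (upper − lower) is narrower than 0.1.
    """
    if len(table) == 0:
        raise ValueError("empty reference table")
    iqr = (table["q3"] - table["q1"]).astype(float).dropna()
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, edges = np.histogram(iqr, bins=edges)
    k = int(np.argmax(counts))
    ci_width = (table["upper"] - table["lower"]).astype(float).dropna()
    return {
        "iqr": iqr,
        "bin_edges": edges,
        "counts": counts,
        "mode": float((edges[k] + edges[k + 1]) / 2.0),
        "ci_width_lt_0.1_fraction": float((ci_width < 0.1).mean()),
    }


def classify_detectability(table: pd.DataFrame, t: float,
                           reportable_low: float) -> pd.DataFrame:
    """Fill the ``detectability`` column of a reference table.

    ``t`` is the aberrance threshold (distance beyond the 95% interval
    required for a call); ``reportable_low`` is the assay's lower
    reportable bound. Inequalities are strict, so a bound exactly at the
    boundary counts as blocked. Loci with missing statistics stay NA.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"t={t} outside (0, 1)")
    out = table.copy()
    lower = out["lower"].astype(float)
    upper = out["upper"].astype(float)
    hyper_ok = (upper + t) < 1.0
    hypo_ok = (lower - t) > max(0.0, reportable_low)
    cls = np.select(
        [hyper_ok & hypo_ok, hyper_ok, hypo_ok],
        ["both", "hyper_only", "hypo_only"],
        default="undetectable",
    )
    out["detectability"] = cls
    out.loc[lower.isna() | upper.isna(), "detectability"] = pd.NA
    return out


def detectability_summary(table: pd.DataFrame) -> dict:
    """Fraction of classified loci that are detectable at all, and the
    fraction of detectable loci callable in one direction only."""
    cls = table["detectability"].dropna()
    if len(cls) == 0:
        raise ValueError("no classified loci")
    detectable = cls.isin(["both", "hyper_only", "hypo_only"])
    one_dir = cls.isin(["hyper_only", "hypo_only"])
    n_det = int(detectable.sum())
    return {
        "n": int(len(cls)),
        "detectable_fraction": float(detectable.mean()),
        "one_direction_fraction": float(one_dir.sum() / n_det) if n_det else float("nan"),
    }


def write_reference_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_reference_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                        keep_default_na=False)
    frame.index = frame.index.astype(str)
    for col in ("min", "q1", "median", "q3", "max", "lower", "upper"):
        frame[col] = frame[col].astype(float)
    frame["n"] = frame["n"].astype(int)
    frame["detectability"] = frame["detectability"].astype(object).where(
        frame["detectability"].notna(), pd.NA
    )
    return frame
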