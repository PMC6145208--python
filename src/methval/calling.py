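"""Aberrant-methylation calling against per-locus reference intervals.

A sample's level at a locus is called *hyper*-aberrant when it exceeds the
reference upper bound by more than the threshold ``t`` (strictly), and
*hypo*-aberrant when it falls more than ``t`` below the reference lower
bound. Levels beneath the assay's lower reportable bound cannot be
quantified exactly — they are known only as "< reportable_low" — so hypo
calls use the worst case: the entire interval [0, reportable_low] must lie
below ``lower − t``. Operationally, hypo iff
``max(beta, reportable_low) < lower − t``.

Boundary equality is never aberrant (conservative). Missing levels or
missing reference statistics yield ``not_evaluable``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "AberrantCallSet",
    "call_sample",
    "aberrant_count",
    "call_set_difference",
    "write_calls",
    "read_calls",
]

STATES = ("normal", "hyper", "hypo", "not_evaluable")


@dataclass
class AberrantCallSet:
    """Per-locus normal/aberrant states for one sample at one threshold."""

    sample_id: str
    calls: pd.Series = field(repr=False)  # locus_id -> state
    t: float = 0.2

    def __post_init__(self) -> None:
        bad = self.calls[~self.calls.isin(STATES)]
        if len(bad):
            raise ValueError(f"invalid call state {bad.iloc[0]!r}")
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate locus ids in call set")

    @property
    def aberrant_loci(self) -> set[str]:
        mask = self.calls.isin(["hyper", "hypo"])
        return set(self.calls.index[mask])

    def __len__(self) -> int:
        return len(self.calls)


def call_sample(beta: pd.Series, reference: pd.DataFrame, t: float,
                reportable_low: float,
                sample_id: str | None = None) -> AberrantCallSet:
    """Call one sample against a reference-interval table.

    ``beta`` is a Series of levels indexed by locus_id; ``reference`` is the
    table from :func:`methval.reference.build_reference` (same loci, any
    order). Raises if the locus universes differ.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"t={t} outside (0, 1)")
    if set(beta.index) != set(reference.index):
        missing = set(beta.index).symmetric_difference(reference.index)
        raise ValueError(
            f"locus mismatch between beta and reference "
            f"({len(missing)} unshared loci, e.g. {sorted(missing)[:3]})"
        )
    ref = reference.loc[beta.index]
    values = beta.to_numpy(dtype=float)
    lower = ref["lower"].to_numpy(dtype=float)
    upper = ref["upper"].to_numpy(dtype=float)

    not_eval = np.isnan(values) | np.isnan(lower) | np.isnan(upper)
    hyper = values > (upper + t)
    # worst-case bound for sub-reportable-range levels
    hypo = np.maximum(values, reportable_low) < (lower - t)
    states = np.select(
        [not_eval, hyper, hypo],
        ["not_evaluable", "hyper", "hypo"],
        default="normal",
    )
    return AberrantCallSet(
        sample_id=sample_id or str(beta.name or "sample"),
        calls=pd.Series(states, index=beta.index, dtype=object),
        t=t,
    )


def aberrant_count(calls: AberrantCallSet) -> int:
    """Number of loci called hyper- or hypo-aberrant."""
    return int(calls.calls.isin(["hyper", "hypo"]).sum())


def call_set_difference(a: AberrantCallSet, b: AberrantCallSet) -> int:
    """Cardinality of the symmetric difference of the two aberrant-locus
    sets. Direction is ignored: a locus aberrant in both replicates counts
    as agreeing even if hyper in one and hypo in the other."""
    if set(a.calls.index) != set(b.calls.index):
        raise ValueError("call sets cover different locus universes")
    return len(a.aberrant_loci ^ b.aberrant_loci)


def write_calls(calls: AberrantCallSet, path) -> None:
    frame = calls.calls.rename("state").to_frame()
    frame.index.name = "locus_id"
    frame.to_csv(path, sep="\t")


def read_calls(path, sample_id: str | None = None,
               t: float = 0.2) -> AberrantCallSet:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return AberrantCallSet(
        sample_id=sample_id or str(path),
        calls=frame["state"].astype(object),
        t=t,
    )
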