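"""Replicate-concordance statistics and proficiency-testing rules.

For ``n`` technical replicates of a sample, let ``x`` be the number of
replicates called aberrant at a CpG. The per-locus similarity is

    S = max(x, n - x) / n,

ranging from 1 (perfect agreement) down to 0.5 (the calling threshold
perfectly bisects the replicates). The per-sample similarity S_jt is the
mean of S over all m evaluated loci — loci never called aberrant in any
replicate contribute S = 1 — and is the empirical probability that a new
replicate's normal/aberrant call at a random CpG is consistent with the
previous calls.

Proficiency testing re-runs known samples and requires each new replicate's
dissimilarity (median pairwise set-difference of aberrant calls against
prior replicates) to stay within ``floor(m * rate * (1 + slack))``;
a run passes when the required fraction of replicates passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import AberrantCallSet, call_sample, call_set_difference
from .methio import BetaMatrix

__all__ = [
    "locus_similarity",
    "sample_similarity",
    "threshold_sweep",
    "pairwise_difference_matrix",
    "pt_evaluate",
    "PrecisionReport",
    "PTOutcome",
]


@dataclass
class PrecisionReport:
    """Replicate-similarity statistics for one sample at one threshold."""

    sample_id: str
    t: float
    n_replicates: int
    m: int                                  # loci evaluated
    s_jt: float
    s_ijt: pd.Series = field(repr=False)    # per-locus similarity
    x_ijt: pd.Series = field(repr=False)    # per-locus aberrant-replicate count
    pairwise_differences: np.ndarray = field(repr=False, default=None)


def locus_similarity(x: int, n: int) -> float:
    """Similarity of aberrant calls at one CpG: max(x, n − x) / n."""
    if n < 1:
        raise ValueError("replicate count n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"aberrant count x={x} outside [0, {n}]")
    return max(x, n - x) / n


def sample_similarity(calls: list[AberrantCallSet],
                      t: float | None = None) -> PrecisionReport:
    """S_jt and its per-locus fragments for one sample's replicates.

    Loci are evaluated with available-case replicate counts; loci not
    evaluable in any replicate are dropped from m.
    """
    if len(calls) < 2:
        raise ValueError("need at least 2 replicates")
    universe = set(calls[0].calls.index)
    for c in calls[1:]:
        if set(c.calls.index) != universe:
            raise ValueError("replicates cover different locus universes")
    t = calls[0].t if t is None else t
    states = pd.DataFrame({i: c.calls for i, c in enumerate(calls)})
    evaluable = (states != "not_evaluable").to_numpy()
    n_i = evaluable.sum(axis=1)
    aberrant = states.isin(["hyper", "hypo"]).to_numpy()
    x_i = (aberrant & evaluable).sum(axis=1)
    keep = n_i >= 1
    if not keep.any():
        raise ValueError("no evaluable loci (m = 0)")
    idx = states.index[keep]
    x = pd.Series(x_i[keep], index=idx, name="x")
    n = n_i[keep]
    s = pd.Series(np.maximum(x.to_numpy(), n - x.to_numpy()) / n, index=idx,
                  name="S")
    return PrecisionReport(
        sample_id=calls[0].sample_id,
        t=t,
        n_replicates=len(calls),
        m=int(keep.sum()),
        s_jt=float(s.mean()),
        s_ijt=s,
        x_ijt=x,
        pairwise_differences=pairwise_difference_matrix(calls),
    )


def pairwise_difference_matrix(calls: list[AberrantCallSet]) -> np.ndarray:
    """Symmetric replicate × replicate matrix of aberrant-set differences."""
    k = len(calls)
    out = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = call_set_difference(calls[i], calls[j])
    return out


def threshold_sweep(replicates: dict[str, BetaMatrix],
                    reference: pd.DataFrame,
                    t_grid: np.ndarray,
                    reportable_low: float) -> pd.DataFrame:
    """S_jt as a function of the calling threshold t.

    ``replicates`` maps sample_id -> BetaMatrix whose columns are that
    sample's technical replicates. Returns a DataFrame indexed by t with
    one column per sample plus a ``mean`` column.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((t_grid <= 0) | (t_grid >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    rows = {}
    for t in t_grid:
        row = {}
        for sample_id, mat in replicates.items():
            calls = [
                call_sample(mat.sample(rep), reference, t, reportable_low,
                            sample_id=f"{sample_id}/{rep}")
                for rep in mat.sample_ids
            ]
            row[sample_id] = sample_similarity(calls, t=t).s_jt
        rows[float(t)] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "t"
    out["mean"] = out.mean(axis=1)
    return out


@dataclass
class PTOutcome:
    """Result of a proficiency-testing evaluation."""

    allowance: int
    per_replicate: pd.DataFrame = field(repr=False)  # statistic + pass flag
    pass_fraction_observed: float = 0.0
    passed: bool = False


def pt_evaluate(new_replicates: list[AberrantCallSet],
                baseline_rate: float, slack: float, pass_fraction: float,
                m: int) -> PTOutcome:
    """Apply the proficiency-testing pass rules to a replicate series.

    Replicates are taken in chronological order; each replicate after the
    first is scored by the median of its pairwise aberrant-set differences
    against all prior replicates. The per-replicate allowance is
    ``floor(m * baseline_rate * (1 + slack))`` differences; the run passes
    if at least ``pass_fraction`` of scored replicates pass.
    """
    if not 0.0 < baseline_rate < 1.0:
        raise ValueError("baseline_rate outside (0, 1)")
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if not 0.0 < pass_fraction <= 1.0:
        raise ValueError("pass_fraction outside (0, 1]")
    if len(new_replicates) < 2:
        raise ValueError("need prior replicates to compare against")
    allowance = math.floor(m * baseline_rate * (1.0 + slack))
    records = []
    for k in range(1, len(new_replicates)):
        diffs = [
            call_set_difference(new_replicates[k], new_replicates[j])
            for j in range(k)
        ]
        stat = float(np.median(diffs))
        records.append(
            {
                "replicate": new_replicates[k].sample_id,
                "median_difference": stat,
                "passed": stat <= allowance,
            }
        )
    detail = pd.DataFrame.from_records(records)
    frac = float(detail["passed"].mean())
    return PTOutcome(
        allowance=allowance,
        per_replicate=detail,
        pass_fraction_observed=frac,
        passed=frac >= pass_fraction,
    )
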