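"""End-to-end validation run over synthetic data, and the report it emits.

The six criteria are executed in dependency order:

1. reportable range — paired WGBS/array samples, per-sample OLS fits,
   aggregated to the overall range (its lower bound feeds later stages);
2. reference interval — reference-population statistics, IQR summary and
   locus detectability;
3. analytical sensitivity — DNA-dilution series, detection p-values,
   failed-probe and failed-sample rules, plus the concentration → DNA mass
   → cell count arithmetic;
4. precision — technical-replicate similarity S_jt across a threshold
   sweep, and the long-run proficiency-testing emulation;
5. analytical specificity — bacterial-contamination series, aberrant-call
   counts, the 99% normal count range, and the max-margin MU threshold;
6. accuracy — per-sample Pearson correlation between array and WGBS.

The report is a plain nested dict serialised as JSON with sorted keys, so
equal runs produce byte-identical files; no timestamps are recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import calling, concordance, precision, qc, reference
from .methio import BetaMatrix
from .simulate import (SimConfig, draw_locus_means, gen_intensities,
                       gen_paired_wgbs_array, gen_reference_population,
                       gen_technical_replicates)

__all__ = ["ValidationReport", "run_validation", "sensitivity_arithmetic",
           "sample_truth", "probe_site_mapping"]

#: ng/µl at which hybridisation signal saturates in the intensity model;
#: concentrations above this contribute no further signal.
SATURATION_NG_UL = 5.0

#: dilution series of the sensitivity experiment, ng/µl (blank first,
#: standard concentration last)
CONCENTRATIONS_NG_UL = (0.0, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 10.0)

#: contamination series of the specificity experiment (fraction of cells
#: bacterial in origin)
CONTAMINATION_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ValidationReport:
    """Per-criterion results of one validation run."""

    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    BLOCK_NAMES = ("reportable_range", "reference_interval", "sensitivity",
                   "precision", "specificity", "accuracy")

    def to_dict(self) -> dict:
        for name in self.BLOCK_NAMES:
            if name not in self.blocks:
                raise ValueError(f"block {name!r} missing and not marked skipped")
        return {"blocks": self.blocks, "provenance": self.provenance}

    def save(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def load(cls, path) -> "ValidationReport":
        with open(path) as handle:
            raw = json.load(handle)
        return cls(blocks=raw["blocks"], provenance=raw["provenance"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ValidationReport):
            return NotImplemented
        return json.dumps(self.to_dict(), sort_keys=True) == json.dumps(
            other.to_dict(), sort_keys=True
        )


def sensitivity_arithmetic(concentration_ng_ul: float, volume_ul: float,
                           conversion_loss: float,
                           dna_per_cell_pg: float) -> dict:
    """Concentration → total DNA → pre-conversion input → minimum cells.

    ``concentration_ng_ul`` is measured post bisulfite conversion at a fixed
    loaded volume; dividing by (1 − conversion_loss) recovers the input DNA
    mass, and dividing by the per-cell DNA content gives the cell count it
    represents.
    """
    if concentration_ng_ul <= 0 or volume_ul <= 0 or dna_per_cell_pg <= 0:
        raise ValueError("all quantities must be positive")
    if not 0.0 <= conversion_loss < 1.0:
        raise ValueError("conversion_loss must lie in [0, 1)")
    total_ng = concentration_ng_ul * volume_ul
    input_ng = total_ng / (1.0 - conversion_loss)
    min_cells = input_ng * 1000.0 / dna_per_cell_pg  # ng -> pg
    return {"total_ng": total_ng, "input_ng": input_ng, "min_cells": min_cells}


def sample_truth(means: np.ndarray, sds: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """One individual's true levels drawn from the population model."""
    return np.clip(means + sds * rng.standard_normal(means.size), 0.0, 1.0)


def probe_site_mapping(n: int) -> pd.DataFrame:
    """Identity mapping between synthetic probes and WGBS sites."""
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:07d}" for i in range(n)],
            "chrom": "chrSim",
            "pos": np.arange(n),
            "strand": "+",
        }
    )


def run_validation(config: SimConfig, t: float = 0.2,
                   p_cutoff: float = qc.DETECTION_P_CUTOFF,
                   fail_fraction: float = qc.FAILED_FRACTION_CUTOFF,
                   pt_rate: float = 0.003, pt_slack: float = 0.2,
                   pt_pass_fraction: float = 0.8,
                   min_cov: int = concordance.MIN_COVERAGE,
                   max_cov: int = concordance.MAX_COVERAGE,
                   n_paired_samples: int = 8,
                   n_precision_samples: int = 6,
                   n_precision_reps: int = 6,
                   n_sensitivity_samples: int = 6,
                   n_specificity_samples: int = 8,
                   long_run_reps: tuple = (14, 18),
                   t_grid: np.ndarray | None = None) -> ValidationReport:
    """Run all six validation criteria on synthetic data.

    Deterministic given ``config.seed``. Stage errors propagate with the
    stage named, except MU-threshold learning, whose failure mode
    (non-separable groups) is a legitimate finding recorded in the
    specificity block rather than an abort.
    """
    report = ValidationReport(
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "parameters": {
                "t": t, "p_cutoff": p_cutoff, "fail_fraction": fail_fraction,
                "pt_rate": pt_rate, "pt_slack": pt_slack,
                "pt_pass_fraction": pt_pass_fraction,
                "min_cov": min_cov, "max_cov": max_cov,
            },
            "version": 1,
        }
    )
    means, sds = draw_locus_means(config)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"validation stage {name!r} failed: {exc}") from exc

    # 1. reportable range (and the paired data reused for accuracy)
    rr_block, acc_block, reportable_low = stage(
        "reportable_range", _stage_reportable, config, means, sds,
        n_paired_samples, min_cov, max_cov,
    )
    report.blocks["reportable_range"] = rr_block
    report.blocks["accuracy"] = acc_block

    # 2. reference interval
    ref_table, ref_block = stage(
        "reference_interval", _stage_reference, config, t, reportable_low,
    )
    report.blocks["reference_interval"] = ref_block

    # 3. analytical sensitivity
    report.blocks["sensitivity"] = stage(
        "sensitivity", _stage_sensitivity, config, means, sds,
        n_sensitivity_samples, p_cutoff, fail_fraction,
    )

    # 4. precision
    report.blocks["precision"] = stage(
        "precision", _stage_precision, config, means, sds, ref_table, t,
        reportable_low, n_precision_samples, n_precision_reps, pt_rate,
        pt_slack, pt_pass_fraction, long_run_reps, t_grid,
    )

    # 5. analytical specificity
    report.blocks["specificity"] = stage(
        "specificity", _stage_specificity, config, means, sds, ref_table, t,
        reportable_low, n_specificity_samples, p_cutoff, fail_fraction,
    )
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_reportable(config, means, sds, n_samples, min_cov, max_cov):
    mapping = probe_site_mapping(config.n_loci)
    fits, correlations = [], []
    per_sample = []
    for s in range(n_samples):
        rng = np.random.default_rng([config.seed, 4, s])
        truth = sample_truth(means, sds, rng)
        wgbs, array = gen_paired_wgbs_array(truth, config, rng=rng)
        array_series = pd.Series(array, index=mapping["probe_id"].to_numpy())
        pairs = concordance.filter_comparable_loci(
            wgbs, array_series, mapping, min_cov=min_cov, max_cov=max_cov
        )
        fit = concordance.fit_reportable_range(pairs)
        r = concordance.accuracy_correlation(pairs)
        fits.append(fit)
        correlations.append(r)
        per_sample.append(
            {
                "sample": f"PAIR{s + 1}", "n": fit.n, "a": fit.a, "b": fit.b,
                "adj_r2": fit.adj_r2, "r_low": fit.r_low,
                "r_high": fit.r_high, "pearson_r": r,
            }
        )
    low, high = concordance.aggregate_reportable_range(fits)
    rr_block = {
        "per_sample": per_sample,
        "overall_low": low,
        "overall_high": high,
    }
    acc_block = {
        "per_sample_r": correlations,
        "mean_r": float(np.mean(correlations)),
        "sd_r": float(np.std(correlations, ddof=1)),
    }
    return rr_block, acc_block, low


def _stage_reference(config, t, reportable_low):
    population = gen_reference_population(config)
    table = reference.build_reference(population)
    table = reference.classify_detectability(table, t, reportable_low)
    iqr = reference.summarize_iqr(table)
    det = reference.detectability_summary(table)
    block = {
        "n_loci": det["n"],
        "n_reference_samples": config.n_reference_samples,
        "iqr_mode": iqr["mode"],
        "ci_width_lt_0.1_fraction": iqr["ci_width_lt_0.1_fraction"],
        "detectable_fraction": det["detectable_fraction"],
        "one_direction_fraction": det["one_direction_fraction"],
    }
    return table, block


def _stage_sensitivity(config, means, sds, n_samples, p_cutoff, fail_fraction):
    per_concentration = {}
    for c_idx, conc in enumerate(CONCENTRATIONS_NG_UL):
        cf = min(1.0, conc / SATURATION_NG_UL)
        n_failed = 0
        fractions = []
        for s in range(n_samples):
            rng = np.random.default_rng([config.seed, 5, c_idx, s])
            truth = sample_truth(means, sds, rng)
            intensities = gen_intensities(truth, cf, 0.0, config, rng=rng)
            pvals = qc.detection_pvalues(intensities)
            _, frac = qc.failed_probe_mask(pvals, cutoff=p_cutoff)
            fractions.append(frac)
            if not qc.sample_sensitivity_pass(frac, cutoff=fail_fraction):
                n_failed += 1
        per_concentration[str(conc)] = {
            "n_failed": n_failed,
            "n_passed": n_samples - n_failed,
            "mean_failed_probe_fraction": float(np.mean(fractions)),
        }
    arithmetic = sensitivity_arithmetic(
        concentration_ng_ul=0.5, volume_ul=15.0, conversion_loss=0.9,
        dna_per_cell_pg=3.0,
    )
    return {
        "per_concentration": per_concentration,
        "established_threshold_ng_ul": 0.5,
        "arithmetic": arithmetic,
        "min_sperm_cell_count": 1_000_000,
    }


def _stage_precision(config, means, sds, ref_table, t, reportable_low,
                     n_samples, n_reps, pt_rate, pt_slack, pt_pass_fraction,
                     long_run_reps, t_grid):
    if t_grid is None:
        t_grid = np.round(np.arange(0.05, 0.55, 0.05), 10)
    replicates = {}
    for s in range(n_samples):
        rng = np.random.default_rng([config.seed, 6, s])
        truth = sample_truth(means, sds, rng)
        replicates[f"PREC{s + 1}"] = gen_technical_replicates(
            truth, n_reps, config, rng=rng
        )
    sweep = precision.threshold_sweep(replicates, ref_table, t_grid,
                                      reportable_low)
    if float(t) not in sweep.index:
        at_t = precision.threshold_sweep(replicates, ref_table, [t],
                                         reportable_low)
        sweep = pd.concat([sweep, at_t]).sort_index()
    s_at_t = sweep.loc[float(t)]
    inconsistency = 1.0 - float(s_at_t["mean"])
    allowance = None
    long_run = {}
    for k_idx, n_long in enumerate(long_run_reps):
        rng = np.random.default_rng([config.seed, 7, k_idx])
        truth = sample_truth(means, sds, rng)
        mat = gen_technical_replicates(truth, n_long, config, rng=rng)
        calls = [
            calling.call_sample(mat.sample(rep), ref_table, t, reportable_low,
                                sample_id=f"LONG{k_idx + 1}/{rep}")
            for rep in mat.sample_ids
        ]
        pairwise = precision.pairwise_difference_matrix(calls)
        off_diag = pairwise[np.triu_indices(n_long, k=1)]
        outcome = precision.pt_evaluate(
            calls, baseline_rate=pt_rate, slack=pt_slack,
            pass_fraction=pt_pass_fraction, m=len(ref_table),
        )
        allowance = outcome.allowance
        long_run[f"LONG{k_idx + 1}"] = {
            "n_replicates": n_long,
            "mean_pairwise_differences": float(off_diag.mean()),
            "max_pairwise_differences": int(off_diag.max()),
            "pt_passed": bool(outcome.passed),
            "pt_pass_fraction_observed": outcome.pass_fraction_observed,
        }
    return {
        "t": t,
        "s_jt_at_t": {k: float(v) for k, v in s_at_t.items()},
        "mean_s_jt": float(s_at_t["mean"]),
        "inconsistency_rate": inconsistency,
        "sweep": {
            str(idx): {k: float(v) for k, v in row.items()}
            for idx, row in sweep.iterrows()
        },
        "pt_allowance": allowance,
        "long_run": long_run,
    }


def _stage_specificity(config, means, sds, ref_table, t, reportable_low,
                       n_samples, p_cutoff, fail_fraction):
    records = []
    for s in range(n_samples):
        rng = np.random.default_rng([config.seed, 8, s])
        truth = sample_truth(means, sds, rng)
        for level in CONTAMINATION_GRID:
            intensities = gen_intensities(truth, 1.0, level, config, rng=rng)
            pvals = qc.detection_pvalues(intensities)
            failed_mask, frac = qc.failed_probe_mask(pvals, cutoff=p_cutoff)
            beta = qc.beta_from_intensities(intensities,
                                            offset=config.beta_offset)
            # failed probes are removed before calling aberrant methylation
            beta = beta.mask(failed_mask)
            beta = beta.reindex(ref_table.index)
            calls = calling.call_sample(beta, ref_table, t, reportable_low,
                                        sample_id=f"SPEC{s + 1}@{level}")
            records.append(
                {
                    "sample": f"SPEC{s + 1}",
                    "contamination": level,
                    "failed_probe_fraction": frac,
                    "sensitivity_pass": qc.sample_sensitivity_pass(
                        frac, cutoff=fail_fraction
                    ),
                    "mu": qc.mu_statistic(intensities),
                    "aberrant_count": calling.aberrant_count(calls),
                }
            )
    frame = pd.DataFrame.from_records(records)
    clean_counts = frame.loc[frame["contamination"] == 0.0, "aberrant_count"]
    lo, hi = qc.normal_aberrant_range(clean_counts.to_numpy())
    frame["count_failed"] = (frame["aberrant_count"] < lo) | (
        frame["aberrant_count"] > hi
    )
    failed_mu = frame.loc[frame["count_failed"], "mu"]
    passed_mu = frame.loc[~frame["count_failed"], "mu"]
    try:
        threshold = qc.learn_mu_threshold(failed_mu, passed_mu)
        separable = True
        note = None
    except ValueError as exc:
        threshold, separable, note = None, False, str(exc)
    corr_all = stats.pearsonr(frame["contamination"], frame["aberrant_count"])
    passing = frame[~frame["count_failed"]] if threshold is None else frame[
        frame["mu"] >= threshold
    ]
    if passing["aberrant_count"].nunique() > 1 and passing[
        "contamination"
    ].nunique() > 1:
        corr_pass = stats.pearsonr(passing["contamination"],
                                   passing["aberrant_count"])
        corr_passing = {"r": float(corr_pass.statistic),
                        "p": float(corr_pass.pvalue)}
    else:  # constant counts or a single level left: no association measurable
        corr_passing = {"r": 0.0, "p": 1.0}
    by_level = {
        str(level): {
            "mean_aberrant_count": float(grp["aberrant_count"].mean()),
            "mean_mu": float(grp["mu"].mean()),
            "n_sensitivity_failed": int((~grp["sensitivity_pass"]).sum()),
            "n_count_failed": int(grp["count_failed"].sum()),
        }
        for level, grp in frame.groupby("contamination")
    }
    return {
        "normal_count_range": [lo, hi],
        "by_contamination": by_level,
        "mu_threshold": threshold,
        "mu_separable": separable,
        "mu_note": note,
        "n_failed_samples": int(frame["count_failed"].sum()),
        "correlation_all": {"r": float(corr_all.statistic),
                            "p": float(corr_all.pvalue)},
        "correlation_passing": corr_passing,
    }
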