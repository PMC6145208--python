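"""Synthetic data with the statistical structure of a sperm-methylation assay.

The generators emulate the four kinds of input the validation pipeline
consumes, with no external data:

* a fertile-reference population whose per-CpG beta distributions are
  strongly unimodal — most loci sit near a hypo-methylated mode (~0.04) or a
  hyper-methylated mode (~0.95), a small fraction have intermediate means,
  and a sliver are broad/noisy (these end up undetectable downstream);
* technical replicates of a sample: truth plus small additive Gaussian
  noise, with occasional heavy-noise outlier replicates;
* paired WGBS/array measurements: WGBS levels are binomial draws at
  realistic read coverage, array levels carry an injected linear distortion
  whose true reportable range the concordance fit must recover;
* per-probe fluorescence intensities whose totals shrink with DNA dilution
  and bacterial contamination, plus background-control probes.

Every generator is deterministic given ``SimConfig.seed``; independent
substreams are derived per generator so outputs do not alias each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .methio import BetaMatrix, IntensityTable, WGBSSiteTable

import pandas as pd

__all__ = [
    "SimConfig",
    "gen_reference_population",
    "gen_technical_replicates",
    "gen_paired_wgbs_array",
    "gen_intensities",
    "draw_locus_means",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic assay.

    Defaults are calibrated to the published operating point of the platform
    under validation: per-locus interquartile ranges peaking near 0.03,
    replicate similarity S_jt above 0.997 at threshold t = 0.2, ~99.7% of
    loci detectable with ~94% of those detectable in one direction only,
    and an injected linear reportable range of [0.052, 1].
    """

    n_loci: int = 6690
    n_reference_samples: int = 156

    # locus-mean mixture
    hypo_fraction: float = 0.60       # loci near the hypo-methylated mode
    mid_fraction: float = 0.05        # intermediate loci (callable both ways)
    broad_fraction: float = 0.003     # noisy loci with very wide intervals
    hypo_mode: float = 0.04
    hyper_mode: float = 0.95
    locus_mean_jitter: float = 0.01   # sd of per-locus shift of the mode

    # between-sample spread; 1.349 * 0.022 targets an IQR mode of ~0.03
    population_sd: float = 0.022
    broad_sd: float = 0.25            # spread at broad loci

    # technical replicates
    replicate_noise_sd: float = 0.01
    outlier_rate: float = 0.05
    outlier_noise_sd: float = 0.10

    # paired WGBS
    coverage_mean: float = 45.0
    coverage_sd: float = 20.0

    # array -> truth linear distortion: array = a* + b* . truth + noise.
    # With a* + b* = 1 the injected true reportable range is [a*, 1].
    array_intercept: float = 0.052
    array_slope: float = 0.948
    array_noise_sd: float = 0.01

    # fluorescence intensity model
    signal_mean: float = 8000.0       # expected probe total at full concentration
    intensity_shape: float = 64.0     # gamma shape of per-probe brightness
    background_mean: float = 200.0
    background_sd: float = 20.0
    gamma: float = 1.9                # intensity decay per unit contamination
    # probe artifacts: a fixed panel of probes whose M/U channels are
    # consistently swapped on every array (bad probes are bad everywhere);
    # optionally a few "marginal" probes that flip per hybridisation
    n_artifact_probes: int = 10
    n_marginal_probes: int = 0
    marginal_swap_prob: float = 0.5
    n_background_controls: int = 600
    beta_offset: float = 100.0        # alpha in beta = M / (M + U + alpha)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("population_sd", "broad_sd", "replicate_noise_sd",
                     "outlier_noise_sd", "coverage_sd", "array_noise_sd",
                     "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("hypo_fraction", "mid_fraction", "broad_fraction",
                     "outlier_rate", "marginal_swap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hypo_fraction + self.mid_fraction + self.broad_fraction > 1.0:
            raise ValueError("locus-class fractions sum to more than 1")
        for name in ("hypo_mode", "hyper_mode"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream for a named generator."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_dict(self) -> dict:
        return asdict(self)


_STREAMS = {
    "locus_means": 1,
    "reference": 2,
    "replicates": 3,
    "paired": 4,
    "intensities": 5,
    "artifact_panel": 6,
}


def _locus_ids(n: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(n)]


def draw_locus_means(config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-locus population means and per-locus spreads.

    Returns ``(means, sds)``. Loci are assigned to the hypo / hyper / mid /
    broad classes in fixed proportions; hypo and hyper means sit at the
    respective mode plus a small jitter, mid means are uniform in
    (0.30, 0.70), broad loci sit at 0.5 with a much larger spread.
    """
    rng = rng or config.rng("locus_means")
    n = config.n_loci
    n_hypo = int(round(n * config.hypo_fraction))
    n_mid = int(round(n * config.mid_fraction))
    n_broad = int(round(n * config.broad_fraction))
    n_hyper = n - n_hypo - n_mid - n_broad

    means = np.empty(n)
    sds = np.full(n, config.population_sd)
    j = 0
    means[j:j + n_hypo] = config.hypo_mode + config.locus_mean_jitter * rng.standard_normal(n_hypo)
    j += n_hypo
    means[j:j + n_hyper] = config.hyper_mode + config.locus_mean_jitter * rng.standard_normal(n_hyper)
    j += n_hyper
    means[j:j + n_mid] = rng.uniform(0.30, 0.70, size=n_mid)
    j += n_mid
    means[j:] = 0.5
    sds[j:] = config.broad_sd
    # interleave classes deterministically so locus order carries no signal
    order = rng.permutation(n)
    return np.clip(means[order], 0.001, 0.999), sds[order]


def gen_reference_population(config: SimConfig) -> BetaMatrix:
    """Simulate the known-fertile reference population.

    Each of ``n_reference_samples`` columns is the per-locus mean plus
    Gaussian between-individual spread, truncated to [0, 1].
    """
    if config.n_reference_samples < 2:
        raise ValueError("need at least 2 reference samples")
    means, sds = draw_locus_means(config)
    rng = config.rng("reference")
    noise = rng.standard_normal((config.n_loci, config.n_reference_samples))
    values = np.clip(means[:, None] + sds[:, None] * noise, 0.0, 1.0)
    return BetaMatrix(
        locus_ids=_locus_ids(config.n_loci),
        sample_ids=[f"REF{j:03d}" for j in range(config.n_reference_samples)],
        values=values,
    )


def gen_technical_replicates(truth: np.ndarray, n_reps: int,
                             config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> BetaMatrix:
    """Simulate technical replicates of one sample.

    Each replicate is ``truth`` plus additive Gaussian noise with sd
    ``replicate_noise_sd``, or — with probability ``outlier_rate`` per
    replicate — the heavier ``outlier_noise_sd``, truncated to [0, 1].
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    truth = np.asarray(truth, dtype=float)
    if truth.min() < 0 or truth.max() > 1:
        raise ValueError("truth levels must lie in [0, 1]")
    rng = rng or config.rng("replicates")
    is_outlier = rng.random(n_reps) < config.outlier_rate
    sds = np.where(is_outlier, config.outlier_noise_sd, config.replicate_noise_sd)
    noise = rng.standard_normal((truth.size, n_reps)) * sds[None, :]
    values = np.clip(truth[:, None] + noise, 0.0, 1.0)
    return BetaMatrix(
        locus_ids=_locus_ids(truth.size),
        sample_ids=[f"rep{k + 1}" for k in range(n_reps)],
        values=values,
    )


def gen_paired_wgbs_array(truth: np.ndarray, config: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[WGBSSiteTable, np.ndarray]:
    """Simulate one sample measured both by WGBS and by the array.

    WGBS: coverage ~ round(Normal(coverage_mean, coverage_sd)) clipped to
    >= 1; level = Binomial(coverage, truth) / coverage. Sites are laid out
    on a single synthetic sequence at consecutive 0-based positions, so the
    i-th site pairs with the i-th array probe.

    Array: ``clip(a* + b* . truth + noise, 0, 1)``. Regressing WGBS on the
    array measurement recovers intercept −a*/b* and slope 1/b*, so the
    implied lower reportable cut-off max(0, −intercept/slope) equals ``a*``
    and the upper one (1 − intercept)/slope equals ``a* + b*``; with the
    defaults a* + b* = 1 the injected reportable range is [a*, 1].
    """
    truth = np.asarray(truth, dtype=float)
    if truth.min() < 0 or truth.max() > 1:
        raise ValueError("truth levels must lie in [0, 1]")
    rng = rng or config.rng("paired")
    n = truth.size
    coverage = np.maximum(
        1, np.rint(rng.normal(config.coverage_mean, config.coverage_sd, size=n))
    ).astype(int)
    wgbs_level = rng.binomial(coverage, truth) / coverage
    frame = pd.DataFrame(
        {
            "chrom": "chrSim",
            "pos": np.arange(n),
            "strand": "+",
            "context": "CpG",
            "level": wgbs_level,
            "coverage": coverage,
        }
    )
    array = config.array_intercept + config.array_slope * truth
    if config.array_noise_sd > 0:
        array = array + rng.normal(0.0, config.array_noise_sd, size=n)
    array = np.clip(array, 0.0, 1.0)
    return WGBSSiteTable(frame), array


def _artifact_mask(config: SimConfig, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of probes whose channels are swapped for this array.

    The fixed artifact panel and the marginal-probe identities depend only
    on the config seed (stream ``artifact_panel``); which marginal probes
    flip is drawn from the per-call ``rng``. The panel is drawn from the
    strongly hypo-/hyper-methylated locus classes, where a swapped channel
    yields a definitive aberrant call at any usable intensity — mirroring
    the consistently aberrant probes real arrays exhibit.
    """
    panel_rng = config.rng("artifact_panel")
    if n == config.n_loci:
        means, _ = draw_locus_means(config)
        eligible = np.flatnonzero((means < 0.2) | (means > 0.8))
    else:  # ad-hoc truth vectors: no locus-class structure to respect
        eligible = np.arange(n)
    n_fixed = min(config.n_artifact_probes, len(eligible))
    n_marg = min(config.n_marginal_probes, max(0, len(eligible) - n_fixed))
    chosen = eligible[
        panel_rng.choice(len(eligible), size=n_fixed + n_marg, replace=False)
    ]
    mask = np.zeros(n, dtype=bool)
    mask[chosen[:n_fixed]] = True
    marginal = chosen[n_fixed:]
    mask[marginal[rng.random(n_marg) < config.marginal_swap_prob]] = True
    return mask


def gen_intensities(truth: np.ndarray, concentration_fraction: float,
                    contamination_fraction: float, config: SimConfig,
                    rng: np.random.Generator | None = None) -> IntensityTable:
    """Simulate one sample's per-probe fluorescence intensities.

    The expected probe total is ``signal_mean * concentration_fraction *
    (1 - gamma * contamination_fraction)``, with gamma-distributed
    per-probe brightness; the total splits between the M and U channels in
    proportion to the truth level, and each channel additionally receives a
    background-fluorescence draw. Background-control probes carry background
    draws only.

    Probe artifacts are emulated as M/U channel swaps: a fixed panel of
    ``n_artifact_probes`` (the same probes on every array generated from a
    given config — bad probes are consistently bad) plus
    ``n_marginal_probes`` that each swap independently with probability
    ``marginal_swap_prob`` per hybridisation.
    """
    if not 0.0 <= concentration_fraction <= 1.0:
        raise ValueError("concentration_fraction outside [0, 1]")
    if not 0.0 <= contamination_fraction <= 1.0:
        raise ValueError("contamination_fraction outside [0, 1]")
    decay = 1.0 - config.gamma * contamination_fraction
    if decay <= 0.0:
        raise ValueError(
            f"gamma * contamination = {config.gamma * contamination_fraction:.3f}"
            " >= 1: intensity model degenerate"
        )
    truth = np.asarray(truth, dtype=float)
    rng = rng or config.rng("intensities")
    n = truth.size
    mean_total = config.signal_mean * concentration_fraction * decay
    if mean_total > 0:
        shape = config.intensity_shape
        total = rng.gamma(shape, mean_total / shape, size=n)
    else:
        total = np.zeros(n)
    m_sig = total * truth
    u_sig = total * (1.0 - truth)
    swap = _artifact_mask(config, n, rng)
    m_sig[swap], u_sig[swap] = u_sig[swap].copy(), m_sig[swap].copy()
    bg = lambda size: rng.normal(config.background_mean, config.background_sd, size)
    M = np.maximum(0.0, m_sig + bg(n))
    U = np.maximum(0.0, u_sig + bg(n))
    ctrl_n = config.n_background_controls
    frame = pd.DataFrame(
        {
            "probe_id": _locus_ids(n) + [f"ctrl{k:04d}" for k in range(ctrl_n)],
            "M": np.concatenate([M, np.maximum(0.0, bg(ctrl_n))]),
            "U": np.concatenate([U, np.maximum(0.0, bg(ctrl_n))]),
            "is_background_control": [False] * n + [True] * ctrl_n,
        }
    )
    return IntensityTable(frame)
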