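# Methods

This note documents the models behind `methval`: what the synthetic data
emulate, the statistical procedures, the numerical conventions, and the
places where the design was genuinely open.

## The measurement model

A methylation array reports, per CpG locus, a *beta value* — the fraction
of DNA molecules methylated at that site, estimated as
`M / (M + U + α)` from methylated (M) and unmethylated (U) fluorescence
intensities with the conventional stabilising offset `α = 100`. The assay
under validation calls *aberrant methylation*: a sample's beta at a locus
compared against a reference interval learned from a known-normal
population, with a fixed margin `t = 0.2` beyond the interval required for
a call. All six validation criteria are statements about this measurement
chain.

## Synthetic data generator (`methval.simulate`)

The generator is the pipeline's study-condition definition, not a test
convenience; its defaults are fixed once and shared by every analysis.

**Locus classes.** Sperm methylomes are strongly bimodal: each CpG has a
tight population distribution near a hypo-methylated mode or a
hyper-methylated one. Loci are assigned to four classes:

| class | fraction | population mean | between-sample sd |
|---|---|---|---|
| hypo  | 0.60 | 0.04 ± 0.01 jitter | 0.022 |
| hyper | 0.347 | 0.95 ± 0.01 jitter | 0.022 |
| mid   | 0.05 | uniform (0.30, 0.70) | 0.022 |
| broad | 0.003 | 0.5 | 0.25 |

The hypo majority reflects that candidate fertility loci skew
hypo-methylated. `population_sd = 0.022` targets a per-locus
interquartile-range mode of `1.349 × 0.022 ≈ 0.03`, the observed
tightness of fertile reference ranges. The small mid class produces loci
callable in both directions (so the one-direction fraction lands near
95% rather than a degenerate 100%), and the broad sliver produces the
~0.3% of loci whose reference range is too wide to permit any call.
Values are Gaussian draws truncated to [0, 1] — chosen over a
logit-normal because the intervals being emulated are tight and far from
overwhelming the truncation; the choice is isolated in one function and
swappable.

**Technical replicates** add Gaussian noise of sd 0.01 to a sample's true
levels; each replicate is independently an outlier (sd 0.10) with
probability 0.05, matching the observation that long replicate series
occasionally contain one or two discordant arrays. Under these defaults
the expected mean replicate similarity at `t = 0.2` is ≈ 0.9996 — above
the 0.997 operating point — with outlier replicates supplying essentially
all of the inconsistency.

**Paired WGBS/array samples.** WGBS coverage is
`round(N(45, 20))` clipped to ≥ 1 — a realistic sequencing spread in
which the 30–100× window keeps roughly three quarters of sites — and the
WGBS level is `Binomial(coverage, truth)/coverage`. The array level is
`clip(a* + b*·truth + N(0, 0.01), 0, 1)` with `a* = 0.052`,
`b* = 0.948`: a linear distortion whose implied reportable range
(regressing WGBS on array and solving for fitted truth 0 and 1) is
exactly `[0.052, 1.0]`. Parameter-recovery tests fit that regression on
large noisy samples and must recover 0.052 within ±0.01.

**Intensities.** A probe's expected total signal is
`signal_mean · concentration_fraction · (1 − γ·contamination_fraction)`
with `signal_mean = 8000`, `γ = 1.9`, and per-probe brightness
`Gamma(shape 64)` (12.5% CV). The total splits M/U by the truth level and
each channel receives an additive background draw `N(200, 20)`;
background-control probes carry background draws only. Bacterial
contamination therefore acts purely as multiplicative intensity decay —
the mechanism by which contaminated samples corrupt beta values without
necessarily failing detection-p QC — with no cross-hybridisation signal.
Probe artifacts are a fixed panel of 10 probes (drawn once per
configuration from the hypo/hyper classes) whose channels are swapped on
every array; consistent bad probes give every clean sample the same
baseline aberrant count, which is what makes a 99% normal-count range
learned from eight clean replicates usable. An optional per-hybridisation
"marginal probe" mechanism exists but defaults to off — independent
per-sample artifact noise makes the 99% range flag ~1% of clean samples
by construction, a behaviour real consistently-bad probes do not show.

**Concentration mapping.** The dilution analysis converts ng/µl to the
generator's `concentration_fraction` as `min(1, conc / 5.0)` — a simple
hybridisation-saturation model in which signal stops increasing above
5 ng/µl. This places the failed/passed boundary between 0.05 and
0.1 ng/µl, an order of magnitude below the conservative 0.5 ng/µl
processing threshold whose DNA-mass arithmetic
(7.5 ng converted → 75 ng input → 25,000 cells) the report carries.

## Statistical procedures

**Reference intervals** (`methval.reference`): per-locus min, quartiles,
max, and the empirical [2.5%, 97.5%] pair, using linear interpolation at
position `(n−1)p` — the mainstream quantile convention; nothing in the
procedure depends on the choice beyond ±1 order statistic. Loci with
fewer than 2 non-missing values are emitted with missing statistics.
Detectability uses strict inequalities (`upper + t < 1`,
`lower − t > max(0, R_low)`), so a bound exactly at a boundary counts as
blocked.

**Aberrant calls** (`methval.calling`): boundary equality is normal, not
aberrant — conservative in the direction of fewer calls. Sub-reportable
betas are bounds: a hypo call requires the entire interval `[0, R_low]`
to clear `lower − t`, i.e. `max(β, R_low) < lower − t`. Call-set
differences are counted over loci, ignoring direction, because a
direction flip at one locus is one discordant locus, not two.

**Precision** (`methval.precision`): `S_jt` averages over all evaluated
loci, including those never called aberrant (they contribute S = 1);
loci not evaluable in some replicates use available-case counts. The
proficiency-testing statistic is the *median* of a replicate's pairwise
differences against all prior replicates — robust to a single bad prior —
and the allowance uses `floor`, again conservative. A deterministic
inequality links the two views of dissimilarity: mean pairwise difference
≤ `2·m·(1 − S_jt)`.

**Detection p-values** (`methval.qc`): the background model is explicit
rather than delegated to array-processing internals: control probes
contribute single-channel background draws (both their M and U columns),
pooled per channel to estimate `(μ̂, σ̂)`; under the null a probe total is
the sum of two background draws, `N(2μ̂, 2σ̂²)`. This keeps the quoted
rules — normal background, p > 0.01 fails a probe, > 5% failed probes
fails a sample — in a testable closed form. The 99% normal range of
aberrant counts is `mean ± z₀.₉₉₅·sd` floored at 0: with ~8 clean
replicates empirical 0.5/99.5 percentiles are meaningless. The MU failure
threshold is the 1-D max-margin separator (midpoint of the gap); when the
groups are not separable the pipeline reports that finding rather than
forcing a cut.

**Concordance** (`methval.concordance`): coverage bounds are inclusive
[30, 100] (reads of the bound conventions differ between "at least 30×"
and "greater than 30"; inclusivity was fixed once). The reportable-range
fit is single-pass OLS by default; an iterative trimmed mode (refit
inside the current range until cut-offs move < 1e-4) exists for data
whose extremes leave the linear regime, but exact synthetic data
reproduce the published-style cut-offs without it. `adj R² =
1 − (1−r²)(n−1)/(n−2)`. Locus pairing is an explicit probe↔site mapping
file; no genome annotation is consulted.

## Problem sizes

All analyses run at 6,690 loci (the candidate-locus panel size), 156
reference methylomes, 6 precision samples × 6 replicates, long-run series
of 14 and 18 replicates, 8 paired WGBS/array samples, a 6-sample × 8-dose
dilution series, and an 8-sample × 6-level contamination grid; the
parameter-recovery fit uses 50,000 paired loci. These sizes put every
Monte-Carlo estimate comfortably inside the tolerances the tests assert
while keeping a full run in seconds.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the validation
procedures rely on: tight unimodal reference distributions, small
replicate noise with rare outliers, binomial WGBS sampling error, linear
array distortion, and contamination-driven intensity decay. It does not
model probe-chemistry differences (type I vs II), chip-position or batch
effects (the validation design handles those by physical stratification,
not computation), genomic coordinates, bacterial cross-hybridisation, or
between-locus correlation. Consequently, green tests demonstrate that the
procedures are implemented correctly and behave as designed under
realistic noise — not that a particular laboratory's array will achieve
these exact operating numbers; establishing that requires the
laboratory's own data, which is precisely the point of the validation
framework.

Two behaviours of the synthetic pipeline are worth flagging. First,
long-run replicate series that happen to contain early outlier replicates
can fail proficiency testing (seed-dependent) — which is the rule working
as intended, not a defect. Second, the fraction of 95% intervals narrower
than 0.1 is ~99.5% on synthetic data versus ~78% on real sperm
methylomes: real arrays include intermediate and noisy loci beyond the
fertility-panel structure emulated here, so this quantity is reproduced
only qualitatively (most intervals are narrow).
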