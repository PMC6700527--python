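# Methods

This note documents the models, conventions and numerical choices behind
`grplate`, and what the synthetic-data generator does and does not emulate.

## The GR statistic

For a treated well, `GR = 2^(log2(x_c/x_0) / log2(x_ctrl/x_0)) − 1`, with
`x_0` the cell count at the time of drug addition and `x_ctrl` the
vehicle-control count at the endpoint. The ratio of log counts is the
treated growth rate expressed as a fraction of the control growth rate, so
GR is invariant to the absolute division rate: multiplying all three counts
by a constant, or scaling the control rate day to day, leaves GR unchanged.
Conventions adopted:

- `x_0` is the mean of the untreated t=0 plate of the same biological
  replicate and is shared across that replicate's treated plates (the
  pre-treatment plate exists precisely because plating counts are too
  unreliable to serve as `x_0`).
- `x_ctrl` is the per-plate mean of vehicle wells (median selectable), so
  plate-level growth effects cancel.
- GR values outside [−1, 1] are retained and flagged, never clipped;
  clipping would bias the standard-error estimates downstream. A treated
  count of exactly 0 returns the limit −1 with a censoring flag.
- Computing GR requires `x_ctrl > x_0`; a dataset whose controls did not
  grow is an error, not a number.

Windowed ("instantaneous") GR from live-cell time courses uses, per 12-h
window advancing in 2-h steps, the OLS slope of log2(count) vs time for the
treated condition and its plate-matched controls, and
`gr_t = 2^(k_treated/k_ctrl) − 1`. Windows with fewer than 3 timepoints or
a non-positive control slope are omitted. For a time-invariant drug and
noise-free data every window equals the endpoint GR.

## Curve fitting and metrics

`GR(c) = gr_inf + (1 − gr_inf)/(1 + (c/gec50)^h)` is fitted to per-
concentration mean GR by bounded least squares (`scipy.optimize.
least_squares`), with `gr_inf ∈ [−1, 1]`, `h ∈ [0.1, 5]`,
`gec50 ∈ [c_min/100, c_max·100]` (optimized as log10), initialized at the
minimum observed GR, `h = 1`, and multi-started from three GEC50 seeds
(c_min, geometric mid-dose, c_max). A nested F-test (3-parameter sigmoid vs
1-parameter flat mean; df = (2, n−3), α = 0.05) decides the flat fallback;
with all-identical GR values the flat model wins with zero residual.

GR50 is solved in closed form, `gr50 = gec50·(0.5/(0.5 − gr_inf))^(1/h)`,
and censored (`greater_than_cmax` / `less_than_cmin`, with the bound stored
as the value) when the curve never crosses 0.5 inside the tested range —
the situation that makes ATP-readout potencies undefined for weakly
responding drugs. GRmax is deliberately the *measured* mean GR at the top
tested dose, not the fitted asymptote, because it depends on where the dose
series was truncated; `gr_inf` is reported separately. GR_AOC is the
trapezoidal integral of (1 − GR) over log10(c), divided by the log10 range,
so 0 = no effect and 1 = complete arrest everywhere. Two adequacy flags
mark unreliable fits: `gec50_out_of_range` (fitted mid-point outside the
tested range) and `no_lower_plateau` (fitted curve at the top dose still
more than 0.1 GR units above its asymptote).

## Replicate-error metrology

SE = σ/√n with the n−1 sample standard deviation, per drug–dose pair.

- **Technical scope**: one SE per (drug, dose, biological replicate) over
  all of that day's technical GR values (wells × plates). With 8 drugs ×
  8 doses × 3 days this yields 192 values.
- **Biological scope**: the technical unit is the *plate-level mean GR*
  (wells averaged per plate first). For each drug–dose pair, every
  combination choosing one unit per biological replicate is enumerated;
  each combination of b values yields one SE with n = b. With t = 3 plates
  and b = 3 days: 3³ = 27 SEs per pair, 1728 over 64 pairs. The plate (not
  the well) is the unit because each combination must represent one
  internally consistent technical measurement per day.

Metric-level SEs apply the same formulas to GRmax, GR_AOC and log10(GR50)
across per-replicate fits; censored GR50 values are excluded with an
exclusion count (an SE over bounds would be meaningless), and a drug with
fewer than two uncensored GR50s reports that SE as unavailable.

Summaries use the linear-interpolation quantile (h = (n−1)p + 1) for the
90th percentile and a Gaussian KDE with Scott's bandwidth on 256 points
spanning [0, 1.1·max]. The density is renormalized to integrate to 1 on its
grid: SE values live near zero, and untruncated Gaussian kernels would
otherwise leak mass below the support. `10^se` converts an SE in
log10(GR50) into the fold-change uncertainty it implies.

## The generative model

The simulator is built to be *exactly* inverted by the GR pipeline: a drug
at dose c scales the control growth rate by `g(c) = log2(1 + GR_true(c))`,
so expected treated counts are `x_0 · 2^(k·g·T)` and a noise-free dataset
round-trips to the true curve to machine precision (this identity is a test).
Defaults mirror the standard protocol: 750 cells/well seeded, 20-h doubling
time (k = 0.05 doublings/h), 72-h treatment, 8 drugs × 8-dose √10-fold
series with per-drug top doses of 1–10 µM, one untreated t=0 plate plus 3
treated plates × 3 wells/condition per biological replicate, 3 biological
replicates, ≥24 randomized vehicle wells per plate on 16×24 plates.

Noise hierarchy (all log-normal, mean-1 where multiplicative on scale):

- `cv_well = 0.05` — multiplicative measurement noise per count, followed by
  integer quantization. Quantization is part of the noise model and is
  skipped when cv = 0, because the noise-free round-trip identity cannot
  hold under rounding. 5% is typical of automated imaging counts.
- `sigma_plate = 0.02`, `sigma_day = 0.05` — growth-rate multipliers shared
  per plate / per day. These cancel in GR by construction (that is the
  statistic's purpose); they are retained because they vary doubling times
  and the leverage of count noise.
- `sigma_day_potency = 0.10` — a per-(day, drug) log-normal multiplier on
  GEC50. This is the biological-variability channel: a shared growth-rate
  multiplier cannot make biological replicates disagree in GR, whereas
  day-to-day potency shifts (cell state, passage effects) do, most strongly
  at intermediate doses — matching the observation that biological error
  has the longer tail. Mean technical SE grows with `cv_well` and mean
  biological SE with `sigma_day_potency` (a monotonicity test).

Time-varying efficacy multiplies the fractional effect by
`(1 − e^(−t/onset_tau)) · e^(−t/adaptation_tau)`; endpoint counts integrate
the instantaneous growth fraction over the treatment (trapezoid on a 0.25-h
grid; exact when both taus are 0). An adapting drug (onset 4 h, adaptation
60 h for the EGFR-inhibitor-like default) therefore shows windowed GR
rising from 24 h to 48 h, while a time-invariant drug's windows agree; the
adaptation time constants are illustrative, not calibrated.

Other components: an edge field multiplies counts by
`1 − edge_frac·max(0, 1 − d/depth)` for edge distance d (default depth 2,
`edge_frac = 0.05` in the default config, emulating residual border
depression); the dead-cell fraction is `baseline + slope·(1 − (GR+1)/2)`
clipped to [0, 0.95] (defaults 0.02 + 0.30), so nuclei = viable/(1 − f)
ties miscounting of dead cells to drug effect; the surrogate (ATP-style)
signal is `viable · (1 + (atp_bias − 1)·effect(c))`, unit for controls, so
an `atp_bias` of 2 (cells arrest and enlarge) inflates surrogate GRmax and
can censor the surrogate GR50 while the count GR50 stays defined. A
separate biphasic truth class models poly-selective inhibitors whose second
decline sits above the conventional dose range; fitting its truncated
series yields a misleadingly benign asymptote, which is how dose-range
inadequacy is exercised end to end.

What the generator does **not** emulate: image segmentation itself (only
its count-level consequences), spatially correlated noise beyond the
deterministic edge field, media-composition or density effects, genetic
drift between centers, and pharmacokinetics. Passing tests therefore show
the *analysis* is correct and calibrated under the stated statistical
structure, not that real plates obey that structure.

## Edge-effect QC

Given a full plate of untreated counts, deviations
`(group mean − plate mean)/plate mean` are reported per row, column and
edge-distance band (0, 1, 2+ with `d = min(row−1, col−1, rows−row,
cols−col)`). Each row/column is tested against all other wells with Welch's
t-test, Bonferroni-corrected across the rows + columns family (40 tests on
a 384-well plate), default α = 0.01 — a deliberately conservative choice
since the appropriate test is not standardized; the false-positive rate on
homogeneous noisy plates is verified ≤ α by simulation. Detection only:
spatial normalization is out of scope, the recommended countermeasure being
randomized dispensing (`randomize_layout`), which converts the systematic
field into random error.

## Problem sizes and reproducibility

The test suite and acceptance script run the full 8-drug design for the
combinatoric and summary checks, 20-seed sweeps for parameter recovery, and
200 simulated plates for QC calibration — sizes chosen so the whole suite
completes in well under a minute while keeping Monte-Carlo assertions
stable. All generators draw from `numpy.random.default_rng(seed)` in a
fixed order; identical (config, seed) pairs produce byte-identical tables,
and the pipeline manifest records output digests so reruns can be verified
file by file.

## Known limitations

- The flat-fallback α, GRmax convention and fit bounds are conventional
  choices; studies using different conventions will differ in edge cases.
- Biological variability is modeled solely as potency jitter; efficacy
  (gr_inf) jitter or correlated drug–day interactions are not modeled.
- The biological-SE enumeration grows as t^b; it is exact, not sampled,
  which is fine for t, b ≤ 5 but would need subsampling beyond that.
- Timecourse generation slows for time-varying drugs (numerical
  integration per timepoint); endpoint generation is closed-form.
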