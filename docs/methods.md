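# Methods

## Signal model

A bioluminescence recording is modeled as a slowly decaying baseline
plus a damped circadian oscillation, both referenced to the onset of
constant darkness (DD) at x = t − t_DD:

    s(x) = B·exp(−k·x) + A·exp(−λ·x)·cos(2π(x − φ)/τ)

| symbol | meaning | unit | default (generator) |
|---|---|---|---|
| B | baseline level | CPS | 300 |
| k | baseline decay (substrate depletion) | 1/h | 0.005 |
| A | oscillation amplitude | CPS | 100 |
| λ | oscillation damping (negative = growing) | 1/h | 0.005 |
| τ | free-running period | h | 24 |
| φ | peak phase relative to DD onset | h | 0 |

The LD entrainment segment is the same cosine continued backwards in
time (x < 0). With φ = 0 and τ ≈ 24 h this places the expression trough
at lights-on of a 12:12 schedule, matching how entrained clock-gene
reporters behave; no acute light-response (masking) transients are
modeled, which is harmless because the analysis discards the first LD
cycle anyway.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies
on: hourly (or finer) sampling over roughly one retained LD cycle plus
four days of DD, damped ~24 h oscillations on a decaying baseline,
counting noise (Poisson on the expected counts by default, since photon
counting is Poisson to first order; Gaussian with fixed SD available
when a controlled noise level is needed), and non-negative counts
(negative expected values are clipped at zero with a logged warning).
Cohorts draw each sample's true period from

    τ(T) = τ_ref · Q10^(−(T − T_ref)/10) + N(0, σ_τ)

so that the full pipeline can be validated against a known Q10.
Per-sample randomness is keyed by a global sample counter
(`SeedSequence(entropy=seed, spawn_key=(i,))`), making cohorts
reproducible regardless of generation order.

Not emulated: luciferin uptake kinetics, tissue geometry or movement
artifacts, temperature effects on the luciferase enzyme itself,
desynchronization among cells within a sample, or the heavy-tailed
outliers real plate wells produce. Passing closed-loop tests therefore
demonstrates that the *analysis* is correct and calibrated for data
that follow its assumed signal model — not that the model captures
every property of real recordings. Amplitude and noise magnitudes are
calibrated only loosely to published mean expression levels (tens to
~1400 CPS).

## Preprocessing

The first LD cycle (default 24 h) is discarded, the DD segment is
extracted and re-zeroed so DD onset is t = 0, and the baseline is
removed by a centered moving average with a 24 h window (subtraction by
default; a divisive mode exists for traces whose amplitude scales with
the baseline). Averaging over exactly one circadian period cancels the
oscillation, so the subtracted trend carries the baseline and the
residuals carry the rhythm.

The trend estimator is the **time-weighted mean** of the
piecewise-linear interpolant over the window (trapezoidal integration
divided by the window span) rather than the plain arithmetic mean of
the samples in the window. On an hourly grid a closed 24 h window
contains 25 samples whose unweighted mean double-counts the window
edges, leaking ~4% of the oscillation into the trend and biasing
amplitudes; the time-weighted mean cancels a full-period cosine exactly
and returns the exact center value for linear trends at interior
points. At the series edges the window truncates (shrinks) rather than
dropping data, so detrended values exist everywhere; edge effects are
confined to the first and last half-window.

## Period fitting

The damped cosine is fitted to the detrended DD residuals by nonlinear
least squares. Two numerical choices matter:

* **Multi-start over τ.** The sum of squares is riddled with local
  minima in τ. The fit evaluates every period on a grid spanning the τ
  bounds (default [16, 40] h in 1 h steps — wide enough for ~20 h
  cool-temperature peripheral rhythms and ~31 h cultured-brain
  rhythms), solving the linear least-squares problem in
  (A·cos, A·sin, offset) at each fixed τ, then refines the five best
  starts with bounded Levenberg–Marquardt-type optimization (analytic
  Jacobian). The refined fit with the lowest SSE wins; exact ties break
  toward the τ nearest 24 h. Damping is bounded in [−0.05, +0.10] /h —
  mildly growing oscillations are allowed because robust peripheral
  oscillators can be non-damping.
* **Operator-matched objective.** The moving average attenuates an
  oscillation by a period-dependent factor and distorts it near the
  truncated edge windows. The fit therefore passes its model through
  the *identical* detrending operator before comparing with the
  detrended data, and excludes the edge half-windows (where the
  truncated window also leaks residual baseline trend, a signal outside
  the model space) from the objective when enough interior data remain.
  Without both, noiseless 30 h traces came back biased by ~1 h; with
  them, noiseless recovery is exact to <0.01 h and the fitted amplitude
  retains its pre-detrend meaning.

Rhythm quality is reported as error = 1 − Pearson r between the fitted
(detrended) curve and the detrended data over the window actually
fitted, so the error lives in [0, 2] and is invariant under positive
affine transforms of either side. Degenerate zero-variance inputs
return error 1 with a warning. The mean expression level is the plain
average of the raw counts over the analyzed window (after the LD
discard, including any retained LD data) — whether published "mean"
levels include the retained LD portion is not determinable, so this
choice is exposed through the preprocessing arguments.

Measured performance of the defaults (96 h DD at 1 h sampling): median
|τ̂ − τ| ≈ 0.13–0.16 h with Gaussian noise at 20% of amplitude, >95% of
arrhythmic (amplitude-zero, Poisson noise) traces rejected at the 0.5
error cutoff, and agreement with a Lomb–Scargle periodogram peak within
one grid bin on noiseless input.

## Group statistics

Fits are filtered at error < 0.5 (cultured tissue) or < 0.7 (whole-fly
recordings, selected by the `whole_fly` tissue label) and only
converged fits are kept. Group summaries report mean ± SEM
(SD with n−1 denominator over √n; SEM is undefined and reported empty
for n = 1). Q10 defaults to the coldest/warmest temperatures present.
Report writers round τ to one decimal and Q10 to two, matching how such
tables are conventionally printed; `q10_from_summary(round_tau_to=1)`
computes Q10 from the printed-precision means so regression comparisons
match like with like, while full precision is retained internally.

## Estimation statistics

Group comparisons are unpaired mean differences (test − control) with
bootstrap resampling: both groups resampled with replacement `n_boot`
times (default 5000), CI by BCa (bias correction from the resample
distribution, acceleration from the within-group jackknife) or plain
percentile. The shared-control design produces one effect size per
non-control group against a common control, resampled independently per
comparison with seeds spawned from one top-level seed — fixed seed,
bit-identical distributions. No multiple-comparison adjustment is
applied; the CIs are reported raw, as is conventional for
shared-control estimation plots.

Calibration, measured here: percentile CI coverage of the null for a
mean difference of normal groups is ~95% at n = 100 per group but only
~93% at n = 40 (scipy's implementation agrees) — the usual small-sample
anticonservatism of the bootstrap. The package's coverage validation
therefore runs at n = 100, inside the asymptotic regime the method
assumes; CIs on groups of a dozen samples should be read as slightly
narrow.

## Problem sizes used in validation

Closed-loop checks use cohorts of 30 samples per temperature at two
temperatures (18/29 °C, τ_ref 21 h, σ_τ 0.25 h, Gaussian noise SD 10
CPS), period recovery uses 200 independent series, arrhythmic rejection
100 seeds, and bootstrap coverage 1000 replicate experiments at
n_boot = 2000 — sizes at which the Monte-Carlo error of each check is
well below its acceptance margin.

## Known limitations

* The exact detrending and fitting conventions of commercial/legacy
  chronobiology packages vary; period estimates are robust to the
  detrending choice but amplitude estimates are not, and should not be
  compared across pipelines.
* Single damped cosine only: waveforms with strong harmonics (sawtooth
  expression profiles) fold harmonic power into the error term.
* No paired designs, standardized effect sizes, or mixed-effects
  modeling of period vs temperature; groups are summarized by their
  means, as the reference tables do.
* The wide plate-reader dialect assumes a shared regular time grid per
  file; vendor binary exports are out of scope.
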