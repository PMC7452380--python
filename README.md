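# lucifit

Period estimation and temperature-compensation statistics for luciferase
reporter bioluminescence rhythms.

## What this solves

Circadian clocks keep ~24 h time in constant conditions and are
*temperature compensated*: their free-running period τ barely changes
across physiological temperatures. Luciferase reporter constructs fused
to clock genes (*per*, *tim*) let clock gene expression be recorded in
real time as photon counts per second (CPS) from cultured tissues or
whole flies in a plate reader. Deciding whether such an oscillator is
compensated requires a chain of analysis steps that `lucifit`
implements end to end:

1. **Trim** the initial light:dark (LD) entrainment cycle and extract
   the free run in constant darkness (DD).
2. **Detrend** the slow baseline (substrate depletion) with a centered
   24 h moving average.
3. **Fit** a damped cosine to the detrended DD trace,

   r(t) ≈ A·e^(−λt)·cos(2π(t − φ)/τ) + c,

   estimating the free-running period τ, amplitude A, damping λ, phase
   φ and offset c. Rhythm quality is the **fit error** = 1 − r(fit,
   data), the complement of the Pearson correlation between fitted
   curve and detrended data (0 = perfect; 1 = no rhythm).
4. **Filter** unreliable fits (error ≥ 0.5 for cultured tissue, ≥ 0.7
   for whole-animal recordings) and summarize groups as mean ± SEM of
   τ, error and mean CPS.
5. **Quantify compensation** with the period Q10 between a cold and a
   warm recording temperature,

   Q10 = (τ_cold / τ_warm)^(10 / (T_warm − T_cold)),

   where Q10 = 1 is perfect compensation and Q10 < 1 means the clock
   slows with warming (over-compensation).
6. **Compare groups** with estimation statistics: unpaired mean
   differences with bootstrap resampling distributions and 95% CIs
   (BCa by default), every group against a shared control (typically
   the coldest temperature).

Because raw plate-reader recordings of the peripheral-clock studies
this pipeline targets are generally unpublished, the package ships a
**synthetic-trace generator** (`lucifit.synth`) that produces LD+DD
recordings with damped oscillations, decaying baselines, Poisson or
Gaussian counting noise, and whole cohorts whose true periods follow a
temperature → period law with a known Q10 — so every stage can be
validated closed-loop against ground truth.

## Worked example

```python
from lucifit import SimParams, analyze_series, simulate_series

params = SimParams(period_h=25.5, amplitude_cps=100, baseline_cps=300,
                   noise_model="poisson")
trace = simulate_series(params, seed=42, sample_id="demo")
fit = analyze_series(trace)
print(f"tau {fit.tau_h:.2f} h, error {fit.error:.3f}")
```

prints

```
tau 25.81 h, error 0.043
```

— the 25.5 h simulated rhythm is recovered to ~0.3 h under Poisson
counting noise, with a fit error far below the 0.5 cutoff. The
`examples/` directory holds one short script per capability
(simulation + fitting, Q10 worked examples on published group means,
the closed-loop pipeline, shared-control estimation statistics); each
prints the numbers it computes and what they mean. Published reference
group summaries for seven Drosophila reporter × tissue combinations are
embedded in `lucifit.datasets`; running
`examples/02_temperature_compensation.py` reproduces, for instance, the
haltere TIM-protein reporter's 4.2 h period lengthening from 18 °C to
29 °C (Q10 = 0.85) against the intact-fly brain-neuron reporter's
Q10 = 1.06.

A thin CLI mirrors the pipeline for batch use:

```sh
lucifit simulate --config design.yaml --seed 1 --out sim/
lucifit fit sim/timeseries.csv --metadata sim/metadata.csv --out fits.csv
lucifit summarize fits.csv --out report.csv
lucifit compare fits.csv --control 18 --out effects.csv
lucifit run --config pipeline.yaml
```

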