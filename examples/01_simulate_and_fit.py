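"""Simulate one luciferase recording and estimate its free-running period.

Generates a 24 h LD + 96 h DD trace with a 25.5 h rhythm and Poisson
counting noise, runs the single-sample chain (discard first LD cycle,
extract DD, detrend, damped-cosine fit) and prints the fit.
"""

from lucifit import SimParams, analyze_series, simulate_series

params = SimParams(
    period_h=25.5,
    amplitude_cps=100.0,
    baseline_cps=300.0,
    damping_per_h=0.005,
    trend_decay_per_h=0.005,
    noise_model="poisson",
)
trace = simulate_series(params, seed=42, sample_id="demo")
fit = analyze_series(trace)

print(f"sample        : {fit.sample_id}")
print(f"period tau    : {fit.tau_h:.2f} h   (simulated: {params.period_h} h)")
print(f"fit error     : {fit.error:.3f}    (1 - correlation; <0.5 passes)")
print(f"amplitude     : {fit.amplitude_cps:.0f} CPS")
print(f"damping       : {fit.damping_per_h:.4f} /h")
print(f"mean level    : {fit.mean_cps:.0f} CPS")
# tau within ~0.1 h of the simulated period and a near-zero error mean the
# trace carries a trustworthy circadian rhythm
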