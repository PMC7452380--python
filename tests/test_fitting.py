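"""Damped-cosine period recovery, the correlation fit error, mean levels."""

import numpy as np
import pytest
from scipy.signal import lombscargle

from lucifit import (
    FitConfig,
    InsufficientDataError,
    SimParams,
    TimeSeries,
    ValidationError,
    analyze_series,
    compute_fit_error,
    fit_damped_cosine,
    mean_level,
    simulate_series,
)
from lucifit.preprocess import DetrendedSeries


def _detrended(t, r, window=None):
    return DetrendedSeries("s", np.asarray(t, float), np.asarray(r, float),
                           np.zeros(len(t)), (t[0], t[-1]), ma_window_h=window)


class TestComputeFitError:
    def test_perfect_fit_is_zero(self):
        x = np.array([1.0, 2.0, 3.0, 2.0])
        assert compute_fit_error(x, x) == pytest.approx(0.0)

    def test_anti_correlated_fit_is_two(self):
        x = np.array([1.0, 2.0, 3.0, 2.0])
        assert compute_fit_error(-x, x) == pytest.approx(2.0)

    def test_orthogonal_sin_cos_is_one(self):
        # brute-force correlation of sin vs cos over whole cycles
        t = np.arange(0, 48, 0.5)
        s, c = np.sin(2 * np.pi * t / 24), np.cos(2 * np.pi * t / 24)
        assert compute_fit_error(s, c) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero variance"):
            err = compute_fit_error(np.ones(5), np.arange(5.0))
        assert err == 1.0

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(size=30)
        base = compute_fit_error(a, b)
        assert compute_fit_error(3.0 * a + 7.0, b) == pytest.approx(base)
        assert compute_fit_error(a, 0.5 * b - 2.0) == pytest.approx(base)

    def test_length_and_size_checks(self):
        with pytest.raises(ValidationError):
            compute_fit_error([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError):
            compute_fit_error([1, 2], [1, 2])


class TestMeanLevel:
    def test_constant_and_two_point_means(self):
        assert mean_level(TimeSeries("a", [0, 1], [100.0, 100.0])) == 100.0
        assert mean_level(TimeSeries("a", [0, 1], [0.0, 100.0])) == 50.0

    def test_matches_analytic_time_average(self):
        # noiseless damped signal: closed-form time average of
        # B·exp(-kt) + A·exp(-lt)·cos(2pi t / tau) over [0, T]
        p = SimParams(
            noise_model="none", ld_hours=0.0, dd_hours=96.0,
            damping_per_h=0.01, trend_decay_per_h=0.005, phase_h=0.0,
        )
        ts = simulate_series(p, seed=0)
        T = p.dd_hours
        k, lam, w = p.trend_decay_per_h, p.damping_per_h, 2 * np.pi / p.period_h
        trend_avg = p.baseline_cps * (1 - np.exp(-k * T)) / (k * T)
        # integral of exp(-lt)cos(wt): [exp(-lt)(w sin wt - l cos wt)/(l^2+w^2)]
        def F(t):
            return np.exp(-lam * t) * (w * np.sin(w * t) - lam * np.cos(w * t))
        osc_avg = p.amplitude_cps * (F(T) - F(0)) / ((lam**2 + w**2) * T)
        expected = trend_avg + osc_avg
        assert mean_level(ts) == pytest.approx(expected, rel=0.01)


class TestFitDampedCosine:
    def test_noiseless_24h_recovered_exactly(self, clean_params):
        fit = analyze_series(simulate_series(clean_params, seed=1))
        assert fit.converged
        assert fit.tau_h == pytest.approx(24.0, abs=0.01)
        assert fit.error < 0.001

    def test_long_period_damped_recovered(self):
        # the slow, damped regime of cultured brains (~30 h)
        p = SimParams(period_h=30.0, damping_per_h=0.01, noise_model="none")
        fit = analyze_series(simulate_series(p, seed=2))
        assert fit.tau_h == pytest.approx(30.0, abs=0.1)

    def test_amplitude_and_damping_recovered_on_clean_data(self):
        p = SimParams(period_h=26.0, damping_per_h=0.008, noise_model="none")
        fit = analyze_series(simulate_series(p, seed=3))
        assert fit.amplitude_cps == pytest.approx(p.amplitude_cps, rel=0.05)
        assert fit.damping_per_h == pytest.approx(0.008, abs=0.002)

    def test_period_invariant_to_scaling_and_offset(self):
        p = SimParams(period_h=25.3, noise_model="gaussian", noise_sd_cps=15.0)
        ts = simulate_series(p, seed=4)
        ref = analyze_series(ts).tau_h
        scaled = ts.with_values(counts_cps=3.0 * ts.counts_cps)
        shifted = ts.with_values(counts_cps=ts.counts_cps + 500.0)
        assert analyze_series(scaled).tau_h == pytest.approx(ref, abs=1e-6)
        assert analyze_series(shifted).tau_h == pytest.approx(ref, abs=1e-3)

    def test_agrees_with_lomb_scargle_oracle(self):
        # independent periodogram peak within one grid bin of the fit
        cfg = FitConfig()
        for tau_true in (21.0, 27.5, 33.0):
            p = SimParams(
                period_h=tau_true, damping_per_h=0.0, trend_decay_per_h=0.0,
                baseline_cps=200.0, noise_model="none", ld_hours=0.0,
                dd_hours=96.0, phase_h=3.0,
            )
            ts = simulate_series(p, seed=0)
            d = _detrended(ts.times_h, ts.counts_cps - ts.counts_cps.mean())
            fit = fit_damped_cosine(d, cfg)
            periods = np.linspace(*cfg.tau_bounds_h, 2000)
            power = lombscargle(
                ts.times_h, ts.counts_cps - ts.counts_cps.mean(),
                2 * np.pi / periods,
            )
            tau_ls = periods[np.argmax(power)]
            assert abs(fit.tau_h - tau_ls) < cfg.tau_grid_step_h

    def test_insufficient_data_rejected(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(InsufficientDataError):
            fit_damped_cosine(_detrended(t, np.cos(t)))
        t = np.arange(0.0, 20.0)  # 16+ points but span < 2 * tau_min
        with pytest.raises(InsufficientDataError):
            fit_damped_cosine(_detrended(t, np.cos(t)))

    def test_parameter_recovery_under_noise(self):
        # reduced-size version of the cohort-level recovery property
        rng = np.random.default_rng(5)
        errors = []
        for _ in range(20):
            tau = rng.uniform(20, 32)
            p = SimParams(
                period_h=tau, noise_model="gaussian", noise_sd_cps=20.0
            )
            fit = analyze_series(
                simulate_series(p, seed=int(rng.integers(2**31)))
            )
            errors.append(abs(fit.tau_h - tau))
        assert np.median(errors) < 0.2
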