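"""The generator's closed form, noise models and cohort period law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lucifit import (
    CohortDesign,
    SimParams,
    ValidationError,
    simulate_arrhythmic,
    simulate_cohort,
    simulate_series,
)
from lucifit.synth import signal_values


class TestSimulateSeries:
    def test_degenerate_flat_series_equals_baseline(self):
        p = SimParams(amplitude_cps=0.0, trend_decay_per_h=0.0, noise_model="none")
        ts = simulate_series(p, seed=0)
        assert np.allclose(ts.counts_cps, p.baseline_cps)

    def test_noiseless_series_matches_closed_form(self, clean_params):
        ts = simulate_series(clean_params, seed=0)
        assert np.array_equal(ts.counts_cps, signal_values(clean_params, ts.times_h))

    def test_successive_maxima_one_period_apart(self):
        p = SimParams(
            period_h=24.0, damping_per_h=0.0, trend_decay_per_h=0.0,
            noise_model="none", sampling_interval_h=0.5,
        )
        ts = simulate_series(p, seed=0)
        dd = ts.counts_cps[ts.times_h >= ts.dd_onset_h]
        # peaks of the undamped cosine: local maxima in the sampled DD trace
        peaks = np.where((dd[1:-1] > dd[:-2]) & (dd[1:-1] > dd[2:]))[0] + 1
        assert len(peaks) >= 3
        assert np.allclose(np.diff(peaks) * p.sampling_interval_h, 24.0)

    def test_seed_reproducibility_and_poisson_mean(self):
        p = SimParams(noise_model="poisson")
        a = simulate_series(p, seed=42)
        b = simulate_series(p, seed=42)
        assert np.array_equal(a.counts_cps, b.counts_cps)
        c = simulate_series(p, seed=43)
        assert not np.array_equal(a.counts_cps, c.counts_cps)
        # Monte-Carlo: mean of many noisy traces within 3 SE of the signal mean
        expected = signal_values(p, a.times_h)
        n_rep = 50
        means = [
            simulate_series(p, seed=s).counts_cps.mean() for s in range(n_rep)
        ]
        se = np.sqrt(expected.mean() / (len(expected) * n_rep))  # Poisson var = mean
        assert abs(np.mean(means) - expected.mean()) < 3 * se

    def test_dd_onset_at_ld_boundary(self, clean_params):
        ts = simulate_series(clean_params, seed=0)
        assert ts.dd_onset_h == clean_params.ld_hours

    @pytest.mark.parametrize(
        "bad",
        [
            {"period_h": -1.0},
            {"amplitude_cps": -5.0},
            {"sampling_interval_h": 7.0},  # >= period/4
            {"dd_hours": 40.0},  # < 2 periods
            {"noise_model": "laplace"},
        ],
    )
    def test_invalid_params_name_the_field(self, bad):
        with pytest.raises(ValidationError) as exc:
            SimParams(**bad)
        assert next(iter(bad)).split("_")[0] in str(exc.value)

    @given(seed=st.integers(0, 2**16), amp=st.floats(0, 500), base=st.floats(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_counts_never_negative(self, seed, amp, base):
        p = SimParams(
            amplitude_cps=amp, baseline_cps=base, noise_model="poisson",
            ld_hours=0.0, dd_hours=48.0,
        )
        ts = simulate_series(p, seed=seed)
        assert np.all(ts.counts_cps >= 0)


class TestArrhythmic:
    def test_noiseless_is_pure_trend(self):
        p = SimParams(noise_model="none")
        ts = simulate_arrhythmic(p, seed=0)
        x = ts.times_h - p.ld_hours
        assert np.allclose(
            ts.counts_cps, p.baseline_cps * np.exp(-p.trend_decay_per_h * x)
        )

    def test_seed_reproducible(self):
        p = SimParams(noise_model="poisson")
        assert np.array_equal(
            simulate_arrhythmic(p, seed=5).counts_cps,
            simulate_arrhythmic(p, seed=5).counts_cps,
        )


class TestCohort:
    def test_flat_q10_gives_equal_expected_periods(self):
        d = CohortDesign(q10_true=1.0, tau_ref_h=24.0)
        assert {d.expected_tau(t) for t in d.temperatures_c} == {24.0}

    def test_expected_tau_matches_q10_law(self):
        # tau_ref 21 h at 18°C with Q10 0.85 gives ~25.11 h at 29°C
        d = CohortDesign(
            temperatures_c=(18.0, 29.0), tau_ref_h=21.0, t_ref_c=18.0,
            q10_true=0.85,
        )
        assert d.expected_tau(29.0) == pytest.approx(21.0 * 0.85 ** (-1.1))
        assert d.expected_tau(29.0) == pytest.approx(25.11, abs=0.005)

    def test_drawn_periods_converge_to_law(self):
        # law of large numbers on the per-sample period draws
        d = CohortDesign(
            temperatures_c=(25.0,), n_per_temperature=10_000, tau_ref_h=24.0,
            t_ref_c=25.0, q10_true=0.9, tau_sd_h=0.5, rng_seed=11,
            base=SimParams(noise_model="none"),
        )
        taus = [float(m.extra["tau_true_h"]) for _, m in simulate_cohort(d)]
        assert abs(np.mean(taus) - 24.0) < 3 * d.tau_sd_h / np.sqrt(len(taus))

    def test_cohort_reproducible_and_metadata_consistent(self):
        d = CohortDesign(
            temperatures_c=(18.0, 29.0), n_per_temperature=3, rng_seed=2
        )
        a = simulate_cohort(d)
        b = simulate_cohort(d)
        assert [m.sample_id for _, m in a] == [m.sample_id for _, m in b]
        for (ts1, m1), (ts2, _) in zip(a, b):
            assert np.array_equal(ts1.counts_cps, ts2.counts_cps)
            assert ts1.temperature_c == m1.temperature_c

    def test_invalid_design_rejected(self):
        with pytest.raises(ValidationError):
            CohortDesign(q10_true=0.0)
        with pytest.raises(ValidationError):
            CohortDesign(n_per_temperature=0)
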