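"""Bootstrap effect sizes: oracles, determinism and coverage behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lucifit import ValidationError, bootstrap_ci, mean_difference, shared_control


class TestMeanDifference:
    def test_identical_groups_give_zero(self):
        assert mean_difference([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_group_mean_period_shift(self):
        # 18°C mean 21.0 h vs 29°C mean 25.2 h: a 4.2 h lengthening
        assert mean_difference([21.0], [25.2]) == pytest.approx(4.2)

    def test_small_arithmetic_example(self):
        assert mean_difference([1, 2], [4, 6]) == pytest.approx(3.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mean_difference([], [1.0])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    )
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry(self, a, b):
        assert mean_difference(a, b) == pytest.approx(-mean_difference(b, a))


def _exhaustive_quantile(control, test, q):
    """Oracle: exact quantile of the resample mean-difference distribution
    by enumerating every ordered resample of both groups."""
    n_c, n_t = len(control), len(test)
    diffs = []
    for c_idx in itertools.product(range(n_c), repeat=n_c):
        c_mean = np.mean([control[i] for i in c_idx])
        for t_idx in itertools.product(range(n_t), repeat=n_t):
            diffs.append(np.mean([test[j] for j in t_idx]) - c_mean)
    diffs = np.sort(diffs)
    # F^{-1}(q): smallest value whose CDF reaches q
    k = int(np.ceil(q * len(diffs))) - 1
    return diffs[max(k, 0)]


class TestBootstrapCI:
    def test_percentile_matches_exhaustive_enumeration(self):
        # groups of 2: 4 x 4 equally likely ordered resamples (3 x 3
        # distinct pairs weighted by multiplicity)
        control, test = np.array([1.0, 2.0]), np.array([4.0, 6.0])
        es = bootstrap_ci(
            control, test, n_boot=40_000, method="percentile", seed=0
        )
        lo = _exhaustive_quantile(control, test, 0.025)
        hi = _exhaustive_quantile(control, test, 0.975)
        # 2.5% falls strictly inside the extreme atoms (mass 1/16 each),
        # so the empirical quantiles converge to them exactly
        assert es.ci_low == pytest.approx(lo, abs=1e-9)
        assert es.ci_high == pytest.approx(hi, abs=1e-9)

    def test_identical_constant_groups_collapse_to_point(self):
        es = bootstrap_ci([5.0, 5.0, 5.0], [5.0, 5.0], n_boot=200, seed=1)
        assert (es.ci_low, es.ci_high) == (0.0, 0.0)
        assert es.mean_difference == 0.0
        assert es.crosses_zero

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        e1 = bootstrap_ci(a, b, n_boot=500, seed=99)
        e2 = bootstrap_ci(a, b, n_boot=500, seed=99)
        assert np.array_equal(e1.resample_distribution, e2.resample_distribution)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci([1.0], [2.0, 3.0])

    def test_crosses_zero_tracks_interval(self):
        rng = np.random.default_rng(3)
        same = bootstrap_ci(rng.normal(0, 1, 30), rng.normal(0, 1, 30), seed=4)
        apart = bootstrap_ci(rng.normal(0, 1, 30), rng.normal(5, 1, 30), seed=4)
        assert same.crosses_zero
        assert not apart.crosses_zero
        assert apart.ci_low <= apart.mean_difference <= apart.ci_high

    def test_agrees_with_scipy_bca(self):
        # independent implementation check on a fixed dataset
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1.2, 20)
        mine = bootstrap_ci(a, b, n_boot=9999, method="bca", seed=6)
        ref = stats.bootstrap(
            (b, a),
            lambda y, x, axis: np.mean(y, axis=axis) - np.mean(x, axis=axis),
            n_resamples=9999, method="BCa", rng=np.random.default_rng(6),
        ).confidence_interval
        assert mine.ci_low == pytest.approx(ref.low, abs=0.08)
        assert mine.ci_high == pytest.approx(ref.high, abs=0.08)

    def test_ci_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(7)
        widths = []
        for n in (10, 40, 160):
            w = []
            for _ in range(30):
                a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
                es = bootstrap_ci(a, b, n_boot=800, method="percentile", seed=rng)
                w.append(es.ci_high - es.ci_low)
            widths.append(np.mean(w))
        # each 4x increase in n should roughly halve the width
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.3)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.3)


class TestSharedControl:
    def test_one_effect_per_noncontrol_group_in_order(self):
        rng = np.random.default_rng(8)
        groups = {f"{t}C": rng.normal(t / 10, 1, 12) for t in (18, 21, 25, 29)}
        effects = shared_control(groups, "18C", n_boot=300, seed=9)
        assert [e.test_label for e in effects] == ["21C", "25C", "29C"]
        assert all(e.control_label == "18C" for e in effects)

    def test_missing_control_rejected(self):
        with pytest.raises(ValidationError, match="16C"):
            shared_control({"18C": [1.0, 2.0]}, "16C")

    def test_control_only_gives_empty_list(self):
        assert shared_control({"18C": [1.0, 2.0]}, "18C") == []

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        groups = {lab: rng.normal(0, 1, 10) for lab in ("a", "b", "c")}
        e1 = shared_control(groups, "a", n_boot=400, seed=11)
        e2 = shared_control(groups, "a", n_boot=400, seed=11)
        for x, y in zip(e1, e2):
            assert np.array_equal(x.resample_distribution, y.resample_distribution)
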