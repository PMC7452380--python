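"""Estimation statistics: bootstrap mean differences with confidence intervals.

Instead of null-hypothesis significance tests, group comparisons are
reported as effect sizes: the unpaired mean difference (test − control)
with a bootstrap resampling distribution and a 95% confidence interval.
In a shared-control design every experimental group is compared against
one common control group (for temperature series, the coldest group),
which is the estimation-statistics analogue of an ANOVA with multiple
comparisons.

The CI is bias-corrected and accelerated (BCa) by default — the
convention of the estimation-statistics literature — with the plain
percentile interval available for cross-checking against exhaustive
resample enumeration. No multiple-comparison adjustment is applied: the
shared-control CIs are reported raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = ["EffectSize", "mean_difference", "bootstrap_ci", "shared_control"]

logger = logging.getLogger(__name__)


@dataclass
class EffectSize:
    """Unpaired mean difference with bootstrap CI."""

    control_label: str
    test_label: str
    mean_difference: float
    ci_low: float
    ci_high: float
    n_control: int
    n_test: int
    n_boot: int
    ci_level: float = 0.95
    method: str = "bca"
    resample_distribution: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def crosses_zero(self) -> bool:
        """True when the CI contains zero, i.e. the groups may share a
        distribution (the analogue of p > 0.05)."""
        return self.ci_low <= 0.0 <= self.ci_high


def mean_difference(control, test) -> float:
    """mean(test) − mean(control)."""
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if control.size == 0 or test.size == 0:
        raise ValidationError("both groups must be non-empty")
    return float(np.mean(test) - np.mean(control))


def _bca_interval(
    dist: np.ndarray,
    observed: float,
    control: np.ndarray,
    test: np.ndarray,
    alpha: float,
) -> tuple[float, float]:
    """BCa quantile levels from the bias z0 and jackknife acceleration.

    The acceleration is estimated from leave-one-out statistics taken
    within each group (the standard multi-sample jackknife)."""
    n_boot = len(dist)
    prop = (np.sum(dist < observed) + 0.5 * np.sum(dist == observed)) / n_boot
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1.0 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)

    jack = []
    sum_c, n_c = control.sum(), len(control)
    sum_t, n_t = test.sum(), len(test)
    for i in range(n_c):
        jack.append(sum_t / n_t - (sum_c - control[i]) / (n_c - 1))
    for j in range(n_t):
        jack.append((sum_t - test[j]) / (n_t - 1) - sum_c / n_c)
    jack = np.asarray(jack)
    diff = jack.mean() - jack
    denom = np.sum(diff**2) ** 1.5
    accel = np.sum(diff**3) / (6.0 * denom) if denom > 0 else 0.0

    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - accel * (z0 + z_alpha))
        out.append(stats.norm.cdf(adj))
    lo_q, hi_q = out
    return (
        float(np.quantile(dist, lo_q)),
        float(np.quantile(dist, hi_q)),
    )


def bootstrap_ci(
    control,
    test,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    method: str = "bca",
    seed: int | np.random.Generator | None = None,
    control_label: str = "control",
    test_label: str = "test",
) -> EffectSize:
    """Bootstrap the unpaired mean difference test − control.

    Both groups are resampled with replacement ``n_boot`` times; the CI
    is BCa (default) or percentile. The resample distribution is returned
    and is bit-identical for a fixed seed.
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(control) < 2 or len(test) < 2:
        raise ValidationError("each group needs n >= 2 for bootstrapping")
    if not (0.0 < ci_level < 1.0):
        raise ValidationError("ci_level must lie in (0, 1)")
    if method not in ("bca", "percentile"):
        raise ValidationError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)

    observed = mean_difference(control, test)
    idx_c = rng.integers(0, len(control), size=(n_boot, len(control)))
    idx_t = rng.integers(0, len(test), size=(n_boot, len(test)))
    dist = test[idx_t].mean(axis=1) - control[idx_c].mean(axis=1)

    alpha = 1.0 - ci_level
    if np.ptp(dist) == 0:
        # all resample differences identical (constant groups): degenerate CI
        lo = hi = float(dist[0])
    elif method == "percentile":
        lo = float(np.quantile(dist, alpha / 2))
        hi = float(np.quantile(dist, 1 - alpha / 2))
    else:
        lo, hi = _bca_interval(dist, observed, control, test, alpha)
    if lo > hi:  # pathological ties can invert BCa quantiles
        logger.warning("BCa interval inverted by ties; swapping bounds")
        lo, hi = hi, lo
    return EffectSize(
        control_label=control_label,
        test_label=test_label,
        mean_difference=observed,
        ci_low=lo,
        ci_high=hi,
        n_control=len(control),
        n_test=len(test),
        n_boot=n_boot,
        ci_level=ci_level,
        method=method,
        resample_distribution=dist,
    )


def shared_control(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    method: str = "bca",
    seed: int | None = None,
) -> list[EffectSize]:
    """One effect size per non-control group against a common control.

    Groups are compared in input order; labels pass through verbatim.
    Resampling is independent per comparison (the control group is
    redrawn each time), seeded reproducibly from ``seed``.
    """
    if control_label not in groups:
        raise ValidationError(
            f"control label {control_label!r} not among groups "
            f"({list(groups)})"
        )
    control = groups[control_label]
    others = [lab for lab in groups if lab != control_label]
    if not others:
        logger.warning("only the control group supplied; nothing to compare")
        return []
    out = []
    for k, lab in enumerate(others):
        child_seed = (
            None
            if seed is None
            else np.random.SeedSequence(entropy=seed, spawn_key=(k,))
        )
        out.append(
            bootstrap_ci(
                control,
                groups[lab],
                n_boot=n_boot,
                ci_level=ci_level,
                method=method,
                seed=np.random.default_rng(child_seed),
                control_label=control_label,
                test_label=lab,
            )
        )
    return out
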