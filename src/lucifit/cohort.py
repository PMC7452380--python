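"""Error filtering, group summaries and temperature-compensation statistics.

Individual period estimates are retained only when the fit error (one
minus the fit/data correlation) is below a cutoff: 0.5 for cultured
tissue recordings and 0.7 for whole-fly recordings, where movement makes
traces noisier. Retained fits are aggregated per genotype × tissue ×
temperature group (mean ± SEM of τ, error and mean CPS, with the sample
SD using the n−1 denominator).

Temperature compensation is quantified by the Q10 of the period:

    Q10 = (τ_cold / τ_warm) ^ (10 / (T_warm − T_cold))

Q10 = 1 means a perfectly compensated clock; Q10 < 1 means the clock
slows down as temperature rises (over-compensation). Equivalently the
same number is the classical rate Q10 computed on frequencies 1/τ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .fitting import FitResult

__all__ = [
    "GroupSummary",
    "Q10Result",
    "FilterResult",
    "default_error_cutoff",
    "filter_fits",
    "summarize_group",
    "summarize_groups",
    "compute_q10",
    "q10_from_summary",
    "delta_tau",
]

logger = logging.getLogger(__name__)

#: Fit-error cutoffs by tissue class: cultured tissue vs whole-animal runs.
TISSUE_CUTOFFS = {"whole_fly": 0.7, "default": 0.5}

GROUP_KEYS = ["genotype", "tissue", "temperature_c"]


def default_error_cutoff(tissue: str) -> float:
    """0.7 for whole-fly recordings, 0.5 for everything else."""
    return TISSUE_CUTOFFS.get(tissue, TISSUE_CUTOFFS["default"])


@dataclass(frozen=True)
class FilterResult:
    kept: list
    n_excluded: int


@dataclass(frozen=True)
class GroupSummary:
    """Per genotype × tissue × temperature aggregate (Table-style row).

    SEM fields are NaN for n = 1 groups (reported empty in CSV output).
    """

    genotype: str
    tissue: str
    temperature_c: float
    n: int
    tau_mean_h: float
    tau_sem_h: float
    error_mean: float
    error_sem: float
    cps_mean: float
    cps_sem: float


@dataclass(frozen=True)
class Q10Result:
    tau_cold_h: float
    t_cold_c: float
    tau_warm_h: float
    t_warm_c: float
    q10: float


def filter_fits(fits: Iterable[FitResult], error_cutoff: float) -> FilterResult:
    """Keep converged fits with error strictly below the cutoff."""
    if not (0.0 < error_cutoff <= 2.0):
        raise ValidationError("error_cutoff must lie in (0, 2]")
    fits = list(fits)
    kept = [f for f in fits if f.converged and f.error < error_cutoff]
    n_excluded = len(fits) - len(kept)
    if fits and not kept:
        logger.warning(
            "all %d fits excluded at error cutoff %.2f", len(fits), error_cutoff
        )
    return FilterResult(kept=kept, n_excluded=n_excluded)


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, np.nan
    return mean, float(np.std(values, ddof=1) / np.sqrt(len(values)))


def summarize_group(
    fits: Sequence[FitResult],
    genotype: str = "",
    tissue: str = "",
    temperature_c: float = np.nan,
) -> GroupSummary:
    """Mean ± SEM of τ, fit error and mean CPS for one group of fits."""
    if not fits:
        raise ValidationError("cannot summarize an empty group")
    tau = np.array([f.tau_h for f in fits])
    err = np.array([f.error for f in fits])
    cps = np.array([f.mean_cps for f in fits])
    tau_m, tau_s = _mean_sem(tau)
    err_m, err_s = _mean_sem(err)
    cps_m, cps_s = _mean_sem(cps)
    return GroupSummary(
        genotype=genotype,
        tissue=tissue,
        temperature_c=float(temperature_c),
        n=len(fits),
        tau_mean_h=tau_m,
        tau_sem_h=tau_s,
        error_mean=err_m,
        error_sem=err_s,
        cps_mean=cps_m,
        cps_sem=cps_s,
    )


def summarize_groups(fits: Iterable[FitResult]) -> list[GroupSummary]:
    """Group fits by (genotype, tissue, temperature) annotations and
    summarize each group; empty input yields an empty list."""
    keyed: dict[tuple, list[FitResult]] = {}
    for f in fits:
        key = (
            f.annotations.get("genotype", ""),
            f.annotations.get("tissue", ""),
            f.temperature_c if f.temperature_c is not None else np.nan,
        )
        keyed.setdefault(key, []).append(f)
    out = []
    for (gen, tis, temp), group in sorted(
        keyed.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        out.append(summarize_group(group, gen, tis, temp))
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def compute_q10(
    tau_cold_h: float, t_cold_c: float, tau_warm_h: float, t_warm_c: float
) -> Q10Result:
    """Temperature coefficient of the period between two temperatures.

    ``q10 = (tau_cold / tau_warm) ** (10 / (t_warm - t_cold))``. Full
    precision is retained internally; report writers round to 2 decimals.
    """
    if t_warm_c <= t_cold_c:
        raise ValidationError(
            f"t_warm_c ({t_warm_c}) must exceed t_cold_c ({t_cold_c})"
        )
    if tau_cold_h <= 0 or tau_warm_h <= 0:
        raise ValidationError("periods must be positive")
    q10 = (tau_cold_h / tau_warm_h) ** (10.0 / (t_warm_c - t_cold_c))
    return Q10Result(
        tau_cold_h=float(tau_cold_h),
        t_cold_c=float(t_cold_c),
        tau_warm_h=float(tau_warm_h),
        t_warm_c=float(t_warm_c),
        q10=float(q10),
    )


def q10_from_summary(
    summaries: Sequence[GroupSummary],
    t_cold_c: float | None = None,
    t_warm_c: float | None = None,
    round_tau_to: int | None = None,
) -> Q10Result:
    """Q10 from the coldest and warmest group τ means (or a given pair).

    ``round_tau_to`` rounds the τ means to that many decimals first, for
    matching tables that print periods at fixed precision.
    """
    if not summaries:
        raise ValidationError("no group summaries supplied")
    temps = {s.temperature_c: s for s in summaries}
    if t_cold_c is None:
        t_cold_c = min(temps)
    if t_warm_c is None:
        t_warm_c = max(temps)
    if t_cold_c not in temps or t_warm_c not in temps:
        raise ValidationError(
            f"temperatures {t_cold_c}/{t_warm_c} not among group summaries "
            f"({sorted(temps)})"
        )
    tau_cold = temps[t_cold_c].tau_mean_h
    tau_warm = temps[t_warm_c].tau_mean_h
    if round_tau_to is not None:
        tau_cold = round(tau_cold, round_tau_to)
        tau_warm = round(tau_warm, round_tau_to)
    return compute_q10(tau_cold, t_cold_c, tau_warm, t_warm_c)


def delta_tau(tau_cold_h: float, tau_warm_h: float) -> float:
    """Signed period change warm minus cold; positive = slows with warmth."""
    if tau_cold_h <= 0 or tau_warm_h <= 0:
        raise ValidationError("periods must be positive")
    return float(tau_warm_h - tau_cold_h)
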