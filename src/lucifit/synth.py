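"""Synthetic bioluminescence traces and cohorts.

The generator emulates plate-reader recordings of luciferase reporter
expression: an LD entrainment segment followed by a free run in constant
darkness (DD), a damped ~24 h cosine riding on an exponentially decaying
baseline (substrate depletion), and photon-counting noise. Time is
recorded in hours from the recording start; the oscillation's clock is
referenced to DD onset, so the closed-form signal is

    signal(x) = baseline · exp(−trend_decay · x)
              + amplitude · exp(−damping · x) · cos(2π (x − phase) / period)

with x = t − dd_onset (negative during the LD segment). With phase = 0
and a near-24 h period, continuing the same cosine backwards puts the
trough at lights-on of a 12:12 schedule, which is where entrained
reporter expression bottoms out.

Cohorts draw each sample's true period from a temperature → period
relation parameterized by a true Q10,

    τ(T) = τ_ref · q10 ^ (−(T − T_ref) / 10) + Normal(0, τ_sd),

so that the full analysis pipeline can be run closed-loop against known
ground truth. One global seed expands to per-sample seeds through a
counter-keyed scheme, making cohorts reproducible regardless of the
order samples are generated in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .core import SampleMetadata, TimeSeries
from .exceptions import ValidationError

__all__ = ["SimParams", "CohortDesign", "simulate_series", "simulate_arrhythmic", "simulate_cohort"]

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

NOISE_MODELS = ("none", "gaussian", "poisson")


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic trace.

    Defaults describe a robust peripheral-tissue recording: a ~24 h
    rhythm of amplitude 100 CPS on a 300 CPS baseline, sampled hourly
    over one retained LD cycle plus four days of DD, with Poisson
    counting noise.
    """

    period_h: float = 24.0
    amplitude_cps: float = 100.0
    damping_per_h: float = 0.005
    phase_h: float = 0.0
    baseline_cps: float = 300.0
    trend_decay_per_h: float = 0.005
    noise_model: str = "poisson"
    noise_sd_cps: float = 20.0
    sampling_interval_h: float = 1.0
    ld_hours: float = 24.0
    dd_hours: float = 96.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValidationError("period_h must be > 0")
        if self.amplitude_cps < 0:
            raise ValidationError("amplitude_cps must be >= 0")
        if self.baseline_cps < 0:
            raise ValidationError("baseline_cps must be >= 0")
        if self.trend_decay_per_h < 0:
            raise ValidationError("trend_decay_per_h must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.noise_model == "gaussian" and self.noise_sd_cps < 0:
            raise ValidationError("noise_sd_cps must be >= 0")
        if self.sampling_interval_h <= 0:
            raise ValidationError("sampling_interval_h must be > 0")
        if self.sampling_interval_h >= self.period_h / 4:
            raise ValidationError(
                "sampling_interval_h must be < period_h / 4 "
                f"({self.sampling_interval_h} >= {self.period_h / 4})"
            )
        if self.ld_hours < 0:
            raise ValidationError("ld_hours must be >= 0")
        if self.dd_hours < 2 * self.period_h:
            raise ValidationError(
                "dd_hours must cover at least two periods "
                f"({self.dd_hours} < {2 * self.period_h})"
            )


def signal_values(params: SimParams, times_h: np.ndarray) -> np.ndarray:
    """Noiseless expected CPS at the given recording times (hours from
    recording start)."""
    x = np.asarray(times_h, dtype=float) - params.ld_hours
    trend = params.baseline_cps * np.exp(-params.trend_decay_per_h * x)
    osc = (
        params.amplitude_cps
        * np.exp(-params.damping_per_h * x)
        * np.cos(TWO_PI * (x - params.phase_h) / params.period_h)
    )
    return trend + osc


def _apply_noise(
    expected: np.ndarray, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    clipped = np.clip(expected, 0.0, None)
    n_neg = int(np.sum(expected < 0))
    if n_neg:
        logger.warning("%d expected counts < 0 clipped to 0", n_neg)
    if params.noise_model == "none":
        return clipped
    if params.noise_model == "poisson":
        return rng.poisson(clipped).astype(float)
    noisy = clipped + rng.normal(0.0, params.noise_sd_cps, size=clipped.shape)
    return np.clip(noisy, 0.0, None)


def simulate_series(
    params: SimParams, seed: int | np.random.SeedSequence | None = None,
    sample_id: str = "sim",
) -> TimeSeries:
    """Generate one synthetic recording.

    The trace spans ``ld_hours + dd_hours`` at the configured sampling
    interval; ``dd_onset_h`` is set to ``ld_hours``. Identical seeds give
    identical traces.
    """
    rng = np.random.default_rng(seed)
    n = int(np.floor((params.ld_hours + params.dd_hours) / params.sampling_interval_h)) + 1
    times = params.sampling_interval_h * np.arange(n, dtype=float)
    counts = _apply_noise(signal_values(params, times), params, rng)
    return TimeSeries(
        sample_id=sample_id,
        times_h=times,
        counts_cps=counts,
        dd_onset_h=params.ld_hours,
        annotations={"synthetic": "true", "noise_model": params.noise_model},
    )


def simulate_arrhythmic(
    params: SimParams, seed: int | np.random.SeedSequence | None = None,
    sample_id: str = "sim-arrhythmic",
) -> TimeSeries:
    """Generate a clock-less (amplitude 0) recording: trend plus noise only.

    Emulates reporter expression in a tissue without a functioning clock,
    which downstream fitting should reject at any sensible error cutoff.
    """
    flat = replace(params, amplitude_cps=0.0)
    ts = simulate_series(flat, seed=seed, sample_id=sample_id)
    ts.annotations["arrhythmic"] = "true"
    return ts


@dataclass(frozen=True)
class CohortDesign:
    """A multi-temperature cohort with a known temperature → period law."""

    temperatures_c: tuple[float, ...] = (18.0, 21.0, 25.0, 29.0)
    n_per_temperature: int = 30
    tau_ref_h: float = 24.0
    t_ref_c: float = 25.0
    q10_true: float = 1.0
    tau_sd_h: float = 0.5
    base: SimParams = field(default_factory=SimParams)
    rng_seed: int = 0
    genotype: str = "sim-luc"
    tissue: str = "haltere"

    def __post_init__(self) -> None:
        if not self.temperatures_c:
            raise ValidationError("temperatures_c must be non-empty")
        if self.n_per_temperature < 1:
            raise ValidationError("n_per_temperature must be >= 1")
        if self.q10_true <= 0:
            raise ValidationError("q10_true must be > 0")
        if self.tau_ref_h <= 0:
            raise ValidationError("tau_ref_h must be > 0")
        if self.tau_sd_h < 0:
            raise ValidationError("tau_sd_h must be >= 0")

    def expected_tau(self, temperature_c: float) -> float:
        """Population mean period at a temperature under the true Q10 law."""
        return self.tau_ref_h * self.q10_true ** (
            -(temperature_c - self.t_ref_c) / 10.0
        )


def simulate_cohort(
    design: CohortDesign,
) -> list[tuple[TimeSeries, SampleMetadata]]:
    """Generate a full cohort of (trace, metadata) pairs.

    Each sample's true period is ``expected_tau(T) + Normal(0, tau_sd_h)``
    and is recorded in the metadata (``tau_true_h``) for recovery tests.
    Per-sample randomness is keyed by a global sample counter, so the
    same ``rng_seed`` always produces the same cohort.
    """
    out: list[tuple[TimeSeries, SampleMetadata]] = []
    counter = 0
    for temp in design.temperatures_c:
        tau_mean = design.expected_tau(temp)
        for k in range(design.n_per_temperature):
            ss = np.random.SeedSequence(
                entropy=design.rng_seed, spawn_key=(counter,)
            )
            tau_ss, trace_ss = ss.spawn(2)
            tau_true = tau_mean + np.random.default_rng(tau_ss).normal(
                0.0, design.tau_sd_h
            )
            tau_true = max(tau_true, 4.0 * design.base.sampling_interval_h * 1.01)
            params = replace(design.base, period_h=float(tau_true))
            sid = f"T{temp:g}_s{k:03d}"
            ts = simulate_series(params, seed=trace_ss, sample_id=sid)
            ts = ts.with_values(temperature_c=float(temp))
            meta = SampleMetadata(
                sample_id=sid,
                genotype=design.genotype,
                tissue=design.tissue,
                temperature_c=float(temp),
                dd_onset_h=params.ld_hours,
                extra={"tau_true_h": f"{tau_true:.6f}"},
            )
            out.append((ts, meta))
            counter += 1
    return out
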