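"""Core containers for bioluminescence recordings.

A :class:`TimeSeries` holds one sample's luminescence trace (counts per
second, CPS) on an hour-based clock that starts at the beginning of the
recording. ``dd_onset_h`` marks the switch from the light:dark (LD)
entrainment segment to constant darkness (DD), the free-running segment
that period fitting operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .exceptions import ValidationError

__all__ = ["TimeSeries", "SampleMetadata"]


@dataclass
class TimeSeries:
    """One sample's timestamped luminescence trace.

    Parameters
    ----------
    sample_id
        Unique identifier of the sample (e.g. a plate well or tissue pair).
    times_h
        Strictly increasing sample times in hours from the recording start.
    counts_cps
        Non-negative photon counts per second, one per time point.
    dd_onset_h
        Hour at which constant darkness (free run) begins. Must lie within
        the recorded time range.
    temperature_c
        Recording temperature in °C, if known.
    annotations
        Free-form string annotations (genotype, tissue, light schedule, ...).
    """

    sample_id: str
    times_h: np.ndarray
    counts_cps: np.ndarray
    dd_onset_h: float = 0.0
    temperature_c: float | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.counts_cps = np.asarray(self.counts_cps, dtype=float)
        if self.times_h.ndim != 1 or self.counts_cps.ndim != 1:
            raise ValidationError("times_h and counts_cps must be 1-D")
        if len(self.times_h) != len(self.counts_cps):
            raise ValidationError(
                f"times_h/counts_cps length mismatch for sample "
                f"{self.sample_id!r}: {len(self.times_h)} != {len(self.counts_cps)}"
            )
        if len(self.times_h) and np.any(np.diff(self.times_h) <= 0):
            raise ValidationError(
                f"times_h must be strictly increasing (sample {self.sample_id!r})"
            )
        if np.any(self.counts_cps < 0):
            raise ValidationError(
                f"counts_cps must be non-negative (sample {self.sample_id!r})"
            )
        if len(self.times_h) and not (
            self.times_h[0] <= self.dd_onset_h <= self.times_h[-1]
        ):
            raise ValidationError(
                f"dd_onset_h={self.dd_onset_h} outside recorded range "
                f"[{self.times_h[0]}, {self.times_h[-1]}] (sample {self.sample_id!r})"
            )

    def __len__(self) -> int:
        return len(self.times_h)

    @property
    def span_h(self) -> float:
        """Total recorded span in hours."""
        return float(self.times_h[-1] - self.times_h[0]) if len(self) else 0.0

    def with_values(self, **changes) -> "TimeSeries":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class SampleMetadata:
    """Experimental annotation of one sample.

    ``tissue`` is one of ``haltere | antenna | brain | whole_fly`` in the
    study design this package models, but any label is accepted; the
    ``whole_fly`` label selects the looser fit-error cutoff downstream.
    """

    sample_id: str
    genotype: str
    tissue: str
    temperature_c: float
    ld_schedule: str = "LD 12:12"
    dd_onset_h: float | None = None
    extra: Mapping[str, str] = field(default_factory=dict)
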