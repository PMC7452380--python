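"""Trim entrainment data, isolate the free run, and detrend.

The standard workflow mirrors how luciferase plate-reader recordings are
prepared for period analysis: the first LD (light:dark) cycle is
discarded because it is dominated by acute light responses, the constant
darkness (DD) segment is extracted and re-zeroed so that DD onset is
t = 0, and a slow baseline — mostly luciferin substrate depletion — is
removed with a centered moving average before curve fitting.

The moving-average window defaults to 24 h: averaging over one full
circadian cycle cancels the oscillation and leaves the baseline, so
subtracting it preserves the circadian band while removing offset and
slow trend. At the edges the window shrinks (is truncated) rather than
dropping half a window of data; edge effects are therefore confined to
the first and last half window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries
from .exceptions import InsufficientDataError, ValidationError

__all__ = ["DetrendedSeries", "discard_initial", "extract_dd", "detrend_moving_average"]


@dataclass
class DetrendedSeries:
    """A detrended trace: ``residuals + trend`` reconstructs the input
    exactly on the retained window (subtract mode)."""

    sample_id: str
    times_h: np.ndarray
    residuals: np.ndarray
    trend: np.ndarray
    window: tuple[float, float]
    mode: str = "subtract"
    #: moving-average window used, if any; lets the fitting stage apply the
    #: identical detrending operator to its model (removes edge bias)
    ma_window_h: float | None = None

    def __len__(self) -> int:
        return len(self.times_h)

    @property
    def span_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0]) if len(self) else 0.0

    def reconstruct(self) -> np.ndarray:
        """Recombine residuals and trend into the original counts."""
        if self.mode == "subtract":
            return self.residuals + self.trend
        return self.residuals * self.trend


def discard_initial(ts: TimeSeries, hours: float) -> TimeSeries:
    """Drop all points earlier than ``hours`` (typically the first LD cycle).

    Times keep the original clock; nothing is re-zeroed.
    """
    if hours < 0:
        raise ValidationError("hours must be >= 0")
    if hours == 0:
        return ts
    keep = ts.times_h >= hours
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"discarding the first {hours} h leaves {int(keep.sum())} point(s) "
            f"of sample {ts.sample_id!r}"
        )
    return ts.with_values(
        times_h=ts.times_h[keep],
        counts_cps=ts.counts_cps[keep],
        dd_onset_h=max(ts.dd_onset_h, float(ts.times_h[keep][0])),
    )


def extract_dd(ts: TimeSeries) -> TimeSeries:
    """Keep only the constant-darkness segment and re-zero its clock.

    All points with ``t >= dd_onset_h`` are retained and times shifted so
    DD onset is t = 0.
    """
    keep = ts.times_h >= ts.dd_onset_h
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"no free-run (DD) data at or after dd_onset_h={ts.dd_onset_h} "
            f"for sample {ts.sample_id!r}"
        )
    return ts.with_values(
        times_h=ts.times_h[keep] - ts.dd_onset_h,
        counts_cps=ts.counts_cps[keep],
        dd_onset_h=0.0,
    )


def detrend_moving_average(
    ts: TimeSeries, window_h: float = 24.0, mode: str = "subtract"
) -> DetrendedSeries:
    """Remove a centered moving-average baseline.

    The trend at time ``t_i`` is the time-weighted mean of the counts
    over ``[t_i - window_h/2, t_i + window_h/2]`` (the window truncates
    at the series edges; see :func:`moving_average_operator`).
    ``mode='subtract'`` returns counts minus trend; ``mode='divide'``
    returns counts divided by trend, for traces whose oscillation
    amplitude scales with the baseline.
    """
    if mode not in ("subtract", "divide"):
        raise ValidationError(f"mode must be 'subtract' or 'divide', got {mode!r}")
    if window_h <= 0:
        raise ValidationError("window_h must be > 0")
    if ts.span_h < window_h:
        raise InsufficientDataError(
            f"series span {ts.span_h:.1f} h is shorter than the detrend window "
            f"{window_h} h; use a smaller window"
        )
    t, y = ts.times_h, ts.counts_cps
    trend = moving_average_operator(t, window_h)(y)
    if mode == "subtract":
        residuals = y - trend
    else:
        if np.any(trend <= 0):
            raise ValidationError(
                "divide-mode detrending requires a strictly positive trend"
            )
        residuals = y / trend
    return DetrendedSeries(
        sample_id=ts.sample_id,
        times_h=t.copy(),
        residuals=residuals,
        trend=trend,
        window=(float(t[0]), float(t[-1])),
        mode=mode,
        ma_window_h=window_h,
    )


def moving_average_operator(times_h: np.ndarray, window_h: float):
    """Centered moving-average operator on the sampling grid of a series.

    Returns a callable mapping sample values to the time-weighted mean of
    their piecewise-linear interpolant over ``[t - window_h/2,
    t + window_h/2]``, truncated at the series edges. The time weighting
    (trapezoidal integration) makes the mean exact for straight lines at
    interior points and cancels a cosine whose period equals the window,
    which a plain arithmetic mean of the samples does not quite do (the
    two window-edge samples would be double-counted).
    """
    t = np.asarray(times_h, dtype=float)
    half = window_h / 2.0
    a = np.clip(t - half, t[0], t[-1])
    b = np.clip(t + half, t[0], t[-1])
    # segment index containing each window edge
    ja = np.clip(np.searchsorted(t, a, side="right") - 1, 0, len(t) - 2)
    jb = np.clip(np.searchsorted(t, b, side="right") - 1, 0, len(t) - 2)
    dt = np.diff(t)

    def apply(values: np.ndarray) -> np.ndarray:
        y = np.asarray(values, dtype=float)
        seg = 0.5 * (y[1:] + y[:-1]) * dt
        cum = np.concatenate([[0.0], np.cumsum(seg)])

        def integral_to(x, j):
            frac = x - t[j]
            yx = y[j] + (y[j + 1] - y[j]) * frac / dt[j]
            return cum[j] + 0.5 * frac * (y[j] + yx)

        return (integral_to(b, jb) - integral_to(a, ja)) / (b - a)

    return apply
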