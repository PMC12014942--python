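"""Spatiotemporal hemodynamics: ROI traces, detrending, cycle averaging,
phase lags and propagation velocity.

The paced-breathing analysis extracts low-frequency hemodynamic
oscillations from a parameter-map time series by removing a polynomial
trend from an ROI-averaged trace, folds cycles at the respiration period,
and measures the phase lag between regions by normalized cross-correlation
with parabolic sub-sample refinement.  A lag over a known center-to-center
distance gives the propagation velocity of the respiratory wave.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .inversion import ParameterMaps
from .optics import InvalidInputError, PARAM_NAMES

__all__ = ["ROITrace", "LagResult", "roi_trace", "detrend", "cycle_average",
           "phase_lag", "wave_velocity"]


@dataclass
class ROITrace:
    """A parameter averaged over a rectangular ROI, frame by frame."""

    times: np.ndarray          # s, uniform spacing
    values: np.ndarray         # parameter units
    channel: str = "thb"
    roi: tuple[int, int, int, int] | None = None   # (y0, y1, x0, x1), pixels
    pixel_pitch_mm: float = 0.05

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidInputError("times and values must align")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise InvalidInputError("times must be strictly increasing "
                                        "and uniformly spaced")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("trace values must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class LagResult:
    lag_s: float
    peak_correlation: float
    resolution_s: float


def roi_trace(frames, roi: tuple[int, int, int, int], channel: str = "thb",
              pixel_pitch_mm: float = 0.05) -> ROITrace:
    """Spatial mean of one channel over a rectangular ROI per frame.

    ``frames`` is a sequence of (time, ParameterMaps[, ...]) tuples as
    produced by the temporal phantom generator, or of (time, array) pairs.
    ``roi`` is (y0, y1, x0, x1) in pixel coordinates (half-open).
    """
    y0, y1, x0, x1 = roi
    times, values = [], []
    ci = PARAM_NAMES.index(channel)
    for frame in frames:
        t, maps = frame[0], frame[1]
        data = maps.data if isinstance(maps, ParameterMaps) else np.asarray(maps)
        ny, nx = data.shape[:2]
        if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise InvalidInputError("ROI outside image bounds")
        times.append(t)
        values.append(float(data[y0:y1, x0:x1, ci].mean()))
    return ROITrace(np.asarray(times), np.asarray(values), channel=channel,
                    roi=roi, pixel_pitch_mm=pixel_pitch_mm)


def detrend(trace: ROITrace, degree: int = 3) -> ROITrace:
    """Subtract the least-squares polynomial of the given degree
    (degree 0 = mean-centering).  Idempotent for a fixed degree."""
    if degree < 0 or degree >= trace.values.size:
        raise InvalidInputError("degree must be in [0, n_samples)")
    t = trace.times - trace.times[0]
    coeffs = np.polynomial.polynomial.polyfit(t, trace.values, degree)
    fit = np.polynomial.polynomial.polyval(t, coeffs)
    return replace(trace, values=trace.values - fit)


def cycle_average(trace: ROITrace, period_s: float) -> np.ndarray:
    """Fold the trace modulo the period and average; the output waveform has
    ``round(period / frame interval)`` samples."""
    n_per = int(round(period_s / trace.dt))
    if trace.values.size < 2 * n_per:
        raise InvalidInputError("trace must span at least two periods")
    n_cycles = trace.values.size // n_per
    folded = trace.values[:n_cycles * n_per].reshape(n_cycles, n_per)
    return folded.mean(axis=0)


def phase_lag(a: ROITrace, b: ROITrace) -> LagResult:
    """Lag of ``b`` relative to ``a`` at the peak of the normalized
    cross-correlation, refined to sub-sample precision by parabolic
    interpolation of the peak.  Positive lag means ``b`` lags ``a``."""
    if a.values.size != b.values.size or abs(a.dt - b.dt) > 1e-9:
        raise InvalidInputError("traces must share length and sampling")
    x = a.values - a.values.mean()
    y = b.values - b.values.mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        raise InvalidInputError("a constant trace has no phase")
    cc = np.correlate(y, x, mode="full") / denom   # index n-1 <-> zero lag
    n = x.size
    k = int(np.argmax(cc))
    # parabolic refinement around the discrete peak
    if 0 < k < cc.size - 1:
        c0, c1, c2 = cc[k - 1], cc[k], cc[k + 1]
        denom2 = c0 - 2 * c1 + c2
        delta = 0.0 if denom2 == 0 else 0.5 * (c0 - c2) / denom2
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    lag = ((k - (n - 1)) + delta) * a.dt
    return LagResult(lag_s=float(lag), peak_correlation=float(cc[k]),
                     resolution_s=a.dt)


def wave_velocity(distance_mm: float, lag_s: float) -> float:
    """Propagation velocity distance / lag, mm/s."""
    if lag_s <= 0:
        raise InvalidInputError("lag must be positive")
    return distance_mm / lag_s
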