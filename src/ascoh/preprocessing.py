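"""Uniform resampling and analysis-window selection for beat-by-beat AS data.

Beat-by-beat series arrive at the (non-uniform) heart rate.  Inter-beat
variation at 70–103 bpm puts the spectral content of interest in the
1–2 Hz band; resampling at 10 Hz oversamples the highest embedded
frequency by a factor of 5.  Resampling is cubic-spline interpolation
(natural boundary), evaluated on a half-open uniform grid
``start + k / rate_hz`` for ``k = 0 .. L*rate - 1``, so a 2000 s window
at 10 Hz yields exactly 20,000 samples.

Window selection skips the initial settling-in period (default 300 s,
where motion artifacts concentrate) and then applies a rolling
median-absolute-deviation (MAD) gate as an automated stand-in for
visual artifact screening; a manual start override is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError
from .synthetic_data import BeatSeries

__all__ = ["WindowSpec", "UniformSeries", "resample_to_uniform", "detect_artifact_free_start"]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window configuration.

    skip_initial_s: leading data to discard (settling-in artifacts).
    window_length_s: analysis span in seconds.
    manual_start_s: explicit start time overriding automatic detection.
    """

    skip_initial_s: float = 300.0
    window_length_s: float = 2000.0
    manual_start_s: float | None = None

    def __post_init__(self):
        if self.skip_initial_s < 0 or (self.manual_start_s is not None and self.manual_start_s < 0):
            raise ValueError("window times must be non-negative")
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly resampled AS trace over one analysis window."""

    patient_id: str
    start_s: float
    rate_hz: float
    values: np.ndarray

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("resampled values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.values.size) / self.rate_hz


def resample_to_uniform(series: BeatSeries, rate_hz: float = 10.0,
                        window: WindowSpec | None = None,
                        start_s: float | None = None) -> UniformSeries:
    """Cubic-spline resample of a beat series onto a uniform grid.

    The interpolant passes through every beat sample exactly.  If
    ``start_s`` is not given, it comes from the window's manual override
    or from :func:`detect_artifact_free_start`.
    """
    window = window or WindowSpec()
    if start_s is None:
        if window.manual_start_s is not None:
            start_s = window.manual_start_s
        else:
            start_s = detect_artifact_free_start(series, window)
    n_samples = int(round(window.window_length_s * rate_hz))
    t = series.times_s
    last_needed = start_s + (n_samples - 1) / rate_hz
    if t[0] > start_s + 1e-9 or t[-1] < last_needed - 1e-9:
        raise InsufficientDataError(
            f"series [{t[0]:.1f}, {t[-1]:.1f}] s does not cover the requested "
            f"window [{start_s:.1f}, {last_needed:.1f}] s "
            f"(short by {max(start_s - t[0], 0):.1f} s at the start, "
            f"{max(last_needed - t[-1], 0):.1f} s at the end)")
    in_win = np.count_nonzero((t >= start_s) & (t <= start_s + window.window_length_s))
    if in_win < 4:
        raise InsufficientDataError(
            f"only {in_win} beats inside the window; cubic-spline resampling needs >= 4")
    spline = CubicSpline(t, series.values, bc_type="natural")
    grid = start_s + np.arange(n_samples) / rate_hz
    return UniformSeries(patient_id=series.patient_id, start_s=float(start_s),
                         rate_hz=float(rate_hz), values=spline(grid))


def detect_artifact_free_start(series: BeatSeries, window: WindowSpec | None = None,
                               mad_factor: float = 5.0, bin_s: float = 30.0,
                               hop_s: float = 10.0) -> float:
    """Earliest start time for an artifact-free analysis window.

    Returns ``manual_start_s`` if set.  Otherwise flags every ``bin_s``
    segment (on a ``hop_s`` sliding grid) whose median absolute
    deviation from the series-wide median exceeds ``mad_factor`` times
    the series-wide MAD, merges flagged segments into bad intervals, and
    returns the earliest time >= ``skip_initial_s`` from which a full
    window fits without touching a bad interval.  Falls back to
    ``skip_initial_s`` with a warning when no window qualifies.
    """
    window = window or WindowSpec()
    if window.manual_start_s is not None:
        return float(window.manual_start_s)
    t, v = series.times_s, series.values
    if t[-1] < window.skip_initial_s + window.window_length_s - 1e-9:
        raise InsufficientDataError(
            f"series ends at {t[-1]:.1f} s; need at least "
            f"{window.skip_initial_s + window.window_length_s:.1f} s "
            "(initial skip + window length)")

    med = np.median(v)
    mad = np.median(np.abs(v - med))
    bad: list[tuple[float, float]] = []
    if mad > 0:
        edges = np.arange(t[0], t[-1] - bin_s + 1e-9, hop_s)
        for b0 in edges:
            i0, i1 = np.searchsorted(t, [b0, b0 + bin_s])
            if i1 - i0 < 5:
                continue
            score = np.median(np.abs(v[i0:i1] - med))
            if score > mad_factor * mad:
                bad.append((float(b0), float(b0 + bin_s)))
    # merge overlapping bad intervals
    merged: list[list[float]] = []
    for b0, b1 in sorted(bad):
        if merged and b0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b1)
        else:
            merged.append([b0, b1])

    candidates = [window.skip_initial_s] + [b1 for _, b1 in merged if b1 > window.skip_initial_s]
    for start in sorted(candidates):
        end = start + window.window_length_s
        if end > t[-1] + 1e-9:
            break
        if all(end <= b0 or start >= b1 for b0, b1 in merged):
            return float(start)
    warnings.warn("no artifact-free window found; falling back to skip_initial_s")
    return float(window.skip_initial_s)
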