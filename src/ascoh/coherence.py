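"""Autocorrelation spectra and coherence features of uniform AS traces.

"Coherence" here means persistence of self-similar structure: a trace
with slow, quasi-periodic modulations keeps large-amplitude oscillatory
autocorrelation coefficients out to long lags, while incoherent noise
decays quickly to small fluctuations around zero.

The normalized autocorrelation uses the biased estimator

    r(k) = c(k) / c(0),  c(k) = (1/N) * sum_i (x_i - xbar) (x_{i+k} - xbar)

which guarantees |r(k)| <= 1 and positive semi-definiteness.  The
discrete coherence statistic integrates |r| over lag times from 100 s
to the end of the spectrum (rectangular rule, half-open interval),
isolating the long-time-scale modulations from short-range structure.
The spectrum is computed by FFT with zero padding to at least 2N, which
is exactly equivalent to the direct O(N^2) sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .errors import DegenerateSignalError
from .preprocessing import UniformSeries

__all__ = [
    "AutocorrSpectrum",
    "CoherenceMetric",
    "ZeroCrossing",
    "autocorrelation_spectrum",
    "coherence_metric",
    "first_zero_crossing",
]


@dataclass(frozen=True)
class AutocorrSpectrum:
    """Normalized autocorrelation coefficients vs. lag time."""

    patient_id: str
    lag_s: np.ndarray
    coeffs: np.ndarray
    estimator: str = "biased, mean-subtracted"

    def __post_init__(self):
        lag = np.asarray(self.lag_s, dtype=float)
        r = np.asarray(self.coeffs, dtype=float)
        if lag.shape != r.shape or lag.ndim != 1 or lag.size < 2:
            raise ValueError("lag_s and coeffs must be equal-length 1-D arrays (>= 2)")
        object.__setattr__(self, "lag_s", lag)
        object.__setattr__(self, "coeffs", r)

    @property
    def lag_step_s(self) -> float:
        return float(self.lag_s[1] - self.lag_s[0])

    def __len__(self) -> int:
        return self.lag_s.size


@dataclass(frozen=True)
class CoherenceMetric:
    """Absolute-area coherence statistic, in seconds (unitless |r| times lag)."""

    patient_id: str
    value: float
    lag_min_s: float = 100.0
    lag_max_s: float = 2000.0


class ZeroCrossing(NamedTuple):
    lag_s: float
    found: bool


def autocorrelation_spectrum(series: UniformSeries) -> AutocorrSpectrum:
    """Normalized autocorrelation of a uniform trace, lags 0 .. (N-1)/rate."""
    x = np.asarray(series.values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    scale = max(1.0, float(np.max(np.abs(series.values))) ** 2)
    if c0 <= 1e-28 * scale:
        raise DegenerateSignalError(
            f"series {series.patient_id!r} has zero variance; coherence is undefined")
    nfft = next_fast_len(2 * n)
    spec = rfft(x, nfft)
    acov = irfft(spec * np.conj(spec), nfft)[:n] / n
    coeffs = acov / acov[0]
    lag = np.arange(n) / series.rate_hz
    return AutocorrSpectrum(patient_id=series.patient_id, lag_s=lag, coeffs=coeffs)


def coherence_metric(spectrum: AutocorrSpectrum, lag_min_s: float = 100.0,
                     lag_max_s: float = 2000.0) -> CoherenceMetric:
    """Integrate |r| over lag times in [lag_min_s, lag_max_s) (rectangular rule)."""
    step = spectrum.lag_step_s
    if not (0 <= lag_min_s < lag_max_s):
        raise ValueError("need 0 <= lag_min_s < lag_max_s")
    if lag_max_s > spectrum.lag_s[-1] + step + 1e-9:
        raise ValueError(
            f"lag_max_s={lag_max_s} exceeds available lags "
            f"(max {spectrum.lag_s[-1]:.3f} s + one step)")
    mask = (spectrum.lag_s >= lag_min_s - 1e-12) & (spectrum.lag_s < lag_max_s - 1e-12)
    value = float(np.sum(np.abs(spectrum.coeffs[mask])) * step)
    return CoherenceMetric(patient_id=spectrum.patient_id, value=value,
                           lag_min_s=float(lag_min_s), lag_max_s=float(lag_max_s))


def first_zero_crossing(spectrum: AutocorrSpectrum) -> ZeroCrossing:
    """Smallest lag > 0 where r changes sign (linear interpolation).

    Returns the maximum lag with ``found=False`` when r never changes sign.
    """
    r = spectrum.coeffs
    lag = spectrum.lag_s
    sign = np.sign(r)
    for k in range(1, r.size):
        if sign[k] == 0.0:
            return ZeroCrossing(float(lag[k]), True)
        if sign[k] != sign[k - 1]:
            frac = r[k - 1] / (r[k - 1] - r[k])
            return ZeroCrossing(float(lag[k - 1] + frac * (lag[k] - lag[k - 1])), True)
    return ZeroCrossing(float(lag[-1]), False)
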