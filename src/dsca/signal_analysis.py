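"""Downstream analyses of blood-flow-index time series.

Welch power spectral density (variance-preserving, one-sided), SNR in dB,
peak-envelope trend extraction and baseline-relative percent change.  These
are the standard post-processing steps applied to BFi traces: the PSD shows
which physiological frequency bands the sampling rate preserves, the
envelope trend turns a pulsatile trace into a slow perfusion trend, and the
percent change quantifies functional activation against a resting baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "PsdEstimate",
    "EnvelopeTrend",
    "welch_psd",
    "snr_db",
    "series_snr_db",
    "envelope_trend",
    "percent_change",
]


@dataclass
class PsdEstimate:
    """One-sided Welch PSD with its segmentation bookkeeping."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int
    segment_length: int
    overlap_fraction: float
    window_name: str

    @property
    def total_power(self) -> float:
        """Trapezoidal integral of the density over frequency."""
        return float(np.trapezoid(self.power, self.frequencies))

    def peak_frequency(self, f_min: float = 0.0) -> float:
        """Frequency of maximum density at or above ``f_min`` (Hz)."""
        sel = self.frequencies >= f_min
        return float(self.frequencies[sel][np.argmax(self.power[sel])])


def welch_psd(
    series,
    sampling_rate: float,
    segment_length: int = 256,
    overlap_fraction: float = 0.5,
    window_name: str = "hann",
) -> PsdEstimate:
    """Averaged-periodogram PSD of a series.

    The series is split into overlapping segments, each windowed and
    Fourier-transformed, and the squared spectra are averaged; one-sided
    density scaling, so the integral over frequency approximates the series
    variance (mean removed per segment).
    """
    x = np.asarray(series, dtype=float)
    if segment_length > x.size:
        raise ValueError(
            f"segment_length {segment_length} exceeds series length {x.size}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    noverlap = int(round(overlap_fraction * segment_length))
    freqs, power = sps.welch(
        x,
        fs=sampling_rate,
        window=window_name,
        nperseg=segment_length,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    step = segment_length - noverlap
    n_segments = 1 + (x.size - segment_length) // step
    return PsdEstimate(
        frequencies=freqs,
        power=power,
        n_segments=n_segments,
        segment_length=segment_length,
        overlap_fraction=overlap_fraction,
        window_name=window_name,
    )


def snr_db(signal_estimate: float, noise_estimate: float) -> float:
    """SNR = 20 log10(S/N) in dB for photon-count amplitudes."""
    if not signal_estimate > 0 or not noise_estimate > 0:
        raise ValueError(
            f"signal and noise estimates must be > 0, got "
            f"S={signal_estimate}, N={noise_estimate}"
        )
    return 20.0 * np.log10(signal_estimate / noise_estimate)


def series_snr_db(series) -> float:
    """SNR of a stationary trace: S = mean, N = standard deviation.

    An operational definition for BFi traces; the raw-count S/N form is
    available through :func:`snr_db` directly.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    return snr_db(float(np.mean(x)), float(np.std(x, ddof=1)))


@dataclass
class EnvelopeTrend:
    """Upper/lower peak envelopes and their midline trend."""

    upper: np.ndarray
    lower: np.ndarray
    trend: np.ndarray
    window: int


def _peak_envelope(x: np.ndarray, window: int, sign: float) -> np.ndarray:
    """Spline through local extrema separated by >= ``window`` samples.

    Endpoints are pinned to the series values so the spline never
    extrapolates.
    """
    n = x.size
    peaks, _ = sps.find_peaks(sign * x, distance=window)
    knots = np.unique(np.concatenate(([0], peaks, [n - 1])))
    if knots.size < 3:
        # too few extrema: linear interpolation between pinned endpoints
        return np.interp(np.arange(n), knots, x[knots])
    return CubicSpline(knots, x[knots])(np.arange(n))


def envelope_trend(series, window: int = 250) -> EnvelopeTrend:
    """Peak-method envelope pair and midline trend of a series.

    Local maxima (minima) at least ``window`` samples apart are spline-
    interpolated into the upper (lower) envelope; the trend is their mean.
    The pair is sorted pointwise afterwards so upper >= lower everywhere,
    which leaves the trend unchanged.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if x.size <= window:
        raise ValueError(f"series length {x.size} must exceed window {window}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite; interpolate gaps first")
    up_raw = _peak_envelope(x, window, +1.0)
    lo_raw = _peak_envelope(x, window, -1.0)
    upper = np.maximum(up_raw, lo_raw)
    lower = np.minimum(up_raw, lo_raw)
    return EnvelopeTrend(
        upper=upper, lower=lower, trend=0.5 * (up_raw + lo_raw), window=window
    )


def percent_change(
    trend_series,
    timestamps=None,
    *,
    sampling_rate: float | None = None,
    baseline_s: float = 8.0,
) -> np.ndarray:
    """Percent change of a trend against its initial-baseline mean.

    100 * (x - x_baseline) / x_baseline with x_baseline the mean of the
    trend over the first ``baseline_s`` seconds.  Provide either
    ``timestamps`` (s) or ``sampling_rate`` (Hz).
    """
    x = np.asarray(trend_series, dtype=float)
    if timestamps is None:
        if sampling_rate is None:
            raise ValueError("provide timestamps or sampling_rate")
        timestamps = np.arange(x.size) / sampling_rate
    t = np.asarray(timestamps, dtype=float)
    sel = t < t[0] + baseline_s
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    base = np.nanmean(x[sel])
    if base == 0 or np.isnan(base):
        raise ValueError("baseline mean must be nonzero")
    return 100.0 * (x - base) / base
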