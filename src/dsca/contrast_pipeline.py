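"""Noise-corrected speckle contrast and blood-flow index from frame stacks.

Processing chain: estimate per-pixel dark statistics from laser-off frames,
flag hot pixels with a single 3-sigma pass on the mean dark image, subtract
the dark offset, compute the ensemble (full-array) squared contrast per
frame, subtract the shot-noise and dark-noise variance contributions,

    kappa_c^2 = (Var(Ic) - sigma_D^2 - <Ic>) / <Ic>^2

and map to a blood-flow index BFi = 1/kappa_c^2, normalized to a baseline
window (rBFi) and optionally smoothed with a centered moving average.

Shot noise enters as a variance equal to the mean corrected intensity
(Poisson statistics, one digital count per photon); read-noise and
quantization terms are identically zero for a photon-counting SPAD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic_frames import FrameStack

__all__ = [
    "DarkStatistics",
    "PixelMask",
    "NoiseBudget",
    "ContrastSeries",
    "estimate_dark_statistics",
    "flag_bad_pixels",
    "corrected_contrast_sq",
    "process_stack",
    "bfi_from_contrast",
    "normalize_bfi",
    "smooth_series",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING_WINDOW = 20
DEFAULT_SIGMA_RULE = 3.0


@dataclass
class DarkStatistics:
    """Per-pixel temporal mean and unbiased variance of dark frames."""

    mean_map: np.ndarray
    var_map: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        self.mean_map = np.asarray(self.mean_map, dtype=float)
        self.var_map = np.asarray(self.var_map, dtype=float)
        if self.mean_map.shape != self.var_map.shape:
            raise ValueError("mean_map and var_map shapes differ")
        if np.any(self.var_map < 0):
            raise ValueError("var_map must be >= 0")

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DarkStatistics":
        """No-dark placeholder (ideal detector or pre-subtracted data)."""
        return cls(np.zeros(shape), np.zeros(shape), 0)


@dataclass
class PixelMask:
    """Boolean validity map; flagged (invalid) pixels are excluded everywhere."""

    valid: np.ndarray
    rule: str = ""

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int((~self.valid).sum())

    @classmethod
    def all_valid(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(np.ones(shape, dtype=bool), rule="none")


@dataclass(frozen=True)
class NoiseBudget:
    """Squared-contrast decomposition: measured = corrected + noise terms.

    kappa_m^2 = kappa_c^2 + kappa_s^2 + kappa_d^2 (+ kappa_r^2 + kappa_q^2,
    both zero for the photon-counting SPAD).
    """

    kappa_m_sq: float
    kappa_s_sq: float
    kappa_d_sq: float
    kappa_c_sq: float
    kappa_r_sq: float = 0.0
    kappa_q_sq: float = 0.0


@dataclass
class ContrastSeries:
    """Per-frame contrast, flow index and provenance of one acquisition."""

    timestamps: np.ndarray
    kappa_m_sq: np.ndarray
    kappa_c_sq: np.ndarray
    mean_intensity: np.ndarray
    bfi: np.ndarray
    rbfi: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name in ("kappa_m_sq", "kappa_c_sq", "mean_intensity", "bfi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.rbfi is not None:
            self.rbfi = np.asarray(self.rbfi, dtype=float)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "time_s": self.timestamps,
                "kappa_m_sq": self.kappa_m_sq,
                "kappa_c_sq": self.kappa_c_sq,
                "bfi": self.bfi,
                "rbfi": self.rbfi if self.rbfi is not None else np.nan,
                "mean_intensity": self.mean_intensity,
            }
        )
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, attrs: dict | None = None) -> "ContrastSeries":
        rbfi = df["rbfi"].to_numpy() if "rbfi" in df else None
        if rbfi is not None and np.all(np.isnan(rbfi)):
            rbfi = None
        return cls(
            timestamps=df["time_s"].to_numpy(),
            kappa_m_sq=df["kappa_m_sq"].to_numpy(),
            kappa_c_sq=df["kappa_c_sq"].to_numpy(),
            mean_intensity=df["mean_intensity"].to_numpy(),
            bfi=df["bfi"].to_numpy(),
            rbfi=rbfi,
            attrs=attrs or {},
        )


def estimate_dark_statistics(dark_stack: FrameStack) -> DarkStatistics:
    """Per-pixel temporal mean and unbiased (ddof=1) variance of dark frames."""
    counts = dark_stack.counts
    if counts.shape[0] < 2:
        raise ValueError(
            f"need >= 2 dark frames to estimate variance, got {counts.shape[0]}"
        )
    arr = counts.astype(float)
    return DarkStatistics(
        mean_map=arr.mean(axis=0),
        var_map=arr.var(axis=0, ddof=1),
        n_frames_used=counts.shape[0],
    )


def flag_bad_pixels(
    reference_image: np.ndarray, n_sigma: float = DEFAULT_SIGMA_RULE
) -> PixelMask:
    """Single-pass sigma rule: flag pixels with |I - mean| > n_sigma * std.

    Mean and standard deviation are taken over all pixels of the reference
    image (typically the mean dark image, where hot pixels stand out).  A
    zero-variance image flags nothing.
    """
    ref = np.asarray(reference_image, dtype=float)
    if not np.all(np.isfinite(ref)):
        raise ValueError("reference image must be finite")
    mu = ref.mean()
    sigma = ref.std(ddof=1) if ref.size > 1 else 0.0
    bad = np.abs(ref - mu) > n_sigma * sigma if sigma > 0 else np.zeros_like(ref, bool)
    return PixelMask(valid=~bad, rule=f"|I - mean| > {n_sigma:g} sigma on reference")


def corrected_contrast_sq(
    frame: np.ndarray,
    dark: DarkStatistics | None = None,
    mask: PixelMask | None = None,
):
    """Measured and noise-corrected squared contrast of a single frame.

    Returns ``(kappa_m_sq, kappa_c_sq, mean_intensity, NoiseBudget)``.
    Variance over valid pixels is the unbiased sample variance.  A
    non-positive mean corrected intensity yields NaN contrasts; a negative
    kappa_c^2 (noise over-subtraction at low signal) is kept as-is and
    flagged by the caller when mapping to BFi.
    """
    frame = np.asarray(frame, dtype=float)
    if dark is None:
        dark = DarkStatistics.zero(frame.shape)
    if mask is None:
        mask = PixelMask.all_valid(frame.shape)
    if frame.shape != dark.mean_map.shape or frame.shape != mask.valid.shape:
        raise ValueError("frame, dark and mask shapes must match")
    valid = mask.valid
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid pixels; contrast undefined")
    ic = frame[valid] - dark.mean_map[valid]
    mean_ic = ic.mean()
    if mean_ic <= 0:
        logger.warning("non-positive mean corrected intensity; contrast undefined")
        nan = float("nan")
        return nan, nan, mean_ic, NoiseBudget(nan, nan, nan, nan)
    var_ic = ic.var(ddof=1)
    dark_var = dark.var_map[valid].mean()
    kappa_m_sq = var_ic / mean_ic**2
    kappa_s_sq = 1.0 / mean_ic  # Poisson: variance = mean, in counts
    kappa_d_sq = dark_var / mean_ic**2
    kappa_c_sq = kappa_m_sq - kappa_s_sq - kappa_d_sq
    budget = NoiseBudget(
        kappa_m_sq=kappa_m_sq,
        kappa_s_sq=kappa_s_sq,
        kappa_d_sq=kappa_d_sq,
        kappa_c_sq=kappa_c_sq,
    )
    return kappa_m_sq, kappa_c_sq, mean_ic, budget


def bfi_from_contrast(kappa_c_sq):
    """Blood-flow index BFi = 1/kappa_c^2; non-positive contrast -> NaN."""
    k = np.asarray(kappa_c_sq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(k > 0, 1.0 / k, np.nan)
    n_bad = int(np.sum(~(k > 0)))
    if n_bad:
        logger.info("bfi_from_contrast: %d non-positive kappa_c^2 -> NaN", n_bad)
    return float(out) if out.ndim == 0 else out


def process_stack(
    stack: FrameStack,
    dark: DarkStatistics | None = None,
    mask: PixelMask | None = None,
    *,
    chunk_frames: int = 256,
) -> ContrastSeries:
    """Run the per-frame contrast chain over a whole stack.

    Vectorized in chunks to bound memory; equivalent to calling
    :func:`corrected_contrast_sq` frame by frame.
    """
    shape = stack.frame_shape
    if dark is None:
        dark = DarkStatistics.zero(shape)
    if mask is None:
        mask = PixelMask.all_valid(shape)
    valid = mask.valid
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError("fewer than 2 valid pixels; contrast undefined")
    dark_var = dark.var_map[valid].mean()
    dmean = dark.mean_map[valid]

    n = stack.n_frames
    kappa_m = np.empty(n)
    kappa_c = np.empty(n)
    mean_i = np.empty(n)
    for start in range(0, n, chunk_frames):
        blk = stack.counts[start : start + chunk_frames].astype(float)
        ic = blk[:, valid] - dmean  # (chunk, n_valid)
        mu = ic.mean(axis=1)
        var = ic.var(axis=1, ddof=1)
        sl = slice(start, start + len(mu))
        mean_i[sl] = mu
        with np.errstate(divide="ignore", invalid="ignore"):
            km = np.where(mu > 0, var / mu**2, np.nan)
            kc = np.where(mu > 0, (var - dark_var - mu) / mu**2, np.nan)
        kappa_m[sl] = km
        kappa_c[sl] = kc

    n_undef = int(np.isnan(kappa_c).sum())
    n_neg = int(np.nansum(kappa_c <= 0))
    logger.info(
        "process_stack: %d frames, %d flagged pixels, %d undefined, "
        "%d non-positive kappa_c^2",
        n, mask.n_flagged, n_undef, n_neg,
    )
    return ContrastSeries(
        timestamps=stack.timestamps,
        kappa_m_sq=kappa_m,
        kappa_c_sq=kappa_c,
        mean_intensity=mean_i,
        bfi=bfi_from_contrast(kappa_c),
        attrs={
            "n_flagged": mask.n_flagged,
            "n_negative_kappa_c_sq": n_neg,
            "dark_var_mean": float(dark_var),
            "rho_mm": stack.rho,
            "exposure_s": stack.exposure_time,
            "frame_rate_fps": stack.frame_rate,
        },
    )


def normalize_bfi(
    series: ContrastSeries, baseline_window: tuple[float, float]
) -> ContrastSeries:
    """Baseline-relative flow index rBFi = BFi / mean(BFi over baseline).

    The baseline mean ignores missing values; by construction the mean of
    rBFi over the baseline window is 1.
    """
    t0, t1 = baseline_window
    sel = (series.timestamps >= t0) & (series.timestamps < t1)
    if not sel.any():
        raise ValueError(
            f"baseline window [{t0}, {t1}) contains no samples "
            f"(series spans [{series.timestamps[0]}, {series.timestamps[-1]}])"
        )
    base = np.nanmean(series.bfi[sel])
    if not base > 0 or math.isnan(base):
        raise ValueError(f"baseline BFi mean must be > 0, got {base}")
    out = replace(series, rbfi=series.bfi / base)
    out.attrs = dict(series.attrs, baseline_window=[t0, t1], baseline_bfi=float(base))
    return out


def smooth(values: np.ndarray, window: int = DEFAULT_SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving average, NaN-aware, window shrinking at the edges."""
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} longer than series ({x.size})")
    if window == 1:
        return x.copy()
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def smooth_series(
    series: ContrastSeries, window: int = DEFAULT_SMOOTHING_WINDOW
) -> ContrastSeries:
    """Apply the centered moving average to every per-frame quantity."""
    out = replace(
        series,
        kappa_m_sq=smooth(series.kappa_m_sq, window),
        kappa_c_sq=smooth(series.kappa_c_sq, window),
        mean_intensity=smooth(series.mean_intensity, window),
        bfi=smooth(series.bfi, window),
        rbfi=None if series.rbfi is None else smooth(series.rbfi, window),
    )
    out.attrs = dict(series.attrs, smoothing_window=window)
    return out
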