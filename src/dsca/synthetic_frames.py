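"""Synthetic SPAD photon-count frames with known speckle statistics.

A fully developed speckle pattern integrated over one exposure has a
gamma-distributed intensity with shape M = 1/kappa^2 (the effective number of
independent speckle fluctuations seen during the exposure).  A photon-counting
pixel then reports a Poisson draw around that latent intensity, so the
observed per-frame ensemble statistics obey the law of total variance

    Var(I) = <I> + <I>^2 / M

and the shot-noise-corrected contrast estimator recovers kappa^2 = 1/M.
Dark counts are Poisson with a per-pixel rate map; a minority of "hot"
pixels carry a multiplied rate, emulating the detector's defect population.

Pixels are statistically independent (one speckle grain per macropixel) and
each frame is an independent speckle realization: frame spacing is assumed
long compared to the field decorrelation time.  Read noise, quantization and
dead-time effects are absent, as they are for a photon-counting SPAD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward_model import (
    FlowParams,
    OpticalProperties,
    SemiInfiniteGeometry,
    speckle_contrast_sq,
)

__all__ = [
    "FrameStack",
    "DarkModel",
    "ScenarioProfile",
    "generate_speckle_frames",
    "generate_dark_frames",
    "generate_scenario_stack",
]

DEFAULT_SHAPE = (128, 128)  # macropixel array
DEFAULT_MEAN_PHOTONS = 10.0  # typical in vivo photon budget per pixel per frame


@dataclass
class FrameStack:
    """Time-ordered photon-count images plus acquisition metadata.

    ``counts`` has shape (n_frames, n_rows, n_cols) and holds non-negative
    integers; ``exposure_time`` (s), ``frame_rate`` (fps) and ``rho`` (mm)
    describe the acquisition; ``metadata`` is free-form provenance (seed,
    scenario, generator version).
    """

    counts: np.ndarray
    exposure_time: float
    frame_rate: float
    rho: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(
                f"counts must be 3-D (frames, rows, cols), got {self.counts.shape}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError(f"counts must be integer, got dtype {self.counts.dtype}")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Frame times in s, spaced at 1/frame_rate starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class DarkModel:
    """Per-pixel dark-count statistics of the detector.

    ``base_rate`` is the expected dark counts per pixel per frame; a fraction
    ``hot_fraction`` of pixels ("hot" pixels) carry ``base_rate *
    hot_multiplier`` instead.  Hot-pixel locations are a fixed property of
    the detector, drawn once from ``detector_seed``, so dark calibration
    stacks and illuminated stacks generated from the same model share the
    same defect map (as they would on real hardware).
    """

    base_rate: float
    hot_fraction: float = 0.0
    hot_multiplier: float = 50.0
    detector_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError(f"base_rate must be >= 0, got {self.base_rate}")
        if not 0 <= self.hot_fraction < 1:
            raise ValueError(f"hot_fraction must be in [0, 1), got {self.hot_fraction}")
        if not self.hot_multiplier > 1:
            raise ValueError(f"hot_multiplier must be > 1, got {self.hot_multiplier}")

    def realize(self, shape: tuple[int, int]):
        """Per-pixel expected dark map and hot mask of this detector."""
        pixel_map = np.full(shape, float(self.base_rate))
        hot_mask = np.zeros(shape, dtype=bool)
        n_hot = int(round(self.hot_fraction * pixel_map.size))
        if n_hot:
            placement = np.random.default_rng(self.detector_seed)
            flat = placement.choice(pixel_map.size, size=n_hot, replace=False)
            hot_mask.flat[flat] = True
            pixel_map[hot_mask] = self.base_rate * self.hot_multiplier
        return pixel_map, hot_mask


def _poisson_counts(rng: np.random.Generator, lam) -> np.ndarray:
    return rng.poisson(lam).astype(np.uint32)


def generate_speckle_frames(
    kappa_sq_target: float,
    mean_photons: float = DEFAULT_MEAN_PHOTONS,
    n_frames: int = 200,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int | None = None,
    *,
    exposure_time: float = 1.6384e-3,
    frame_rate: float = 361.7,
    rho: float = 20.0,
    dark_map: np.ndarray | None = None,
) -> FrameStack:
    """Gamma-Poisson speckle frames with a known contrast ground truth.

    Per pixel and frame, a latent intensity is drawn from a gamma
    distribution with shape M = 1/kappa_sq_target and mean ``mean_photons``,
    then the count is Poisson around it.  Optional ``dark_map`` adds
    per-pixel Poisson dark counts on top.
    """
    if not 0 < kappa_sq_target <= 1:
        raise ValueError(
            f"kappa_sq_target must be in (0, 1], got {kappa_sq_target}"
        )
    if mean_photons < 0:
        raise ValueError(f"mean_photons must be >= 0, got {mean_photons}")
    rng = np.random.default_rng(seed)
    full = (int(n_frames),) + tuple(shape)
    if mean_photons == 0:
        counts = np.zeros(full, dtype=np.uint32)
    else:
        m = 1.0 / kappa_sq_target
        latent = rng.gamma(shape=m, scale=mean_photons / m, size=full)
        counts = _poisson_counts(rng, latent)
    if dark_map is not None:
        counts = counts + _poisson_counts(rng, np.broadcast_to(dark_map, full))
    return FrameStack(
        counts=counts.astype(np.uint32),
        exposure_time=exposure_time,
        frame_rate=frame_rate,
        rho=rho,
        metadata={
            "seed": seed,
            "scenario": "constant",
            "kappa_sq_target": kappa_sq_target,
            "mean_photons": mean_photons,
            "generator": "dsca.synthetic_frames",
        },
    )


def generate_dark_frames(
    dark: DarkModel,
    n_frames: int = 1000,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int | None = None,
    *,
    exposure_time: float = 1.6384e-3,
    frame_rate: float = 361.7,
) -> FrameStack:
    """Laser-off Poisson dark frames; hot-pixel indices land in metadata."""
    rng = np.random.default_rng(seed)
    pixel_map, hot_mask = dark.realize(tuple(shape))
    full = (int(n_frames),) + tuple(shape)
    counts = _poisson_counts(rng, np.broadcast_to(pixel_map, full))
    return FrameStack(
        counts=counts,
        exposure_time=exposure_time,
        frame_rate=frame_rate,
        rho=0.0,
        metadata={
            "seed": seed,
            "scenario": "dark",
            "base_rate": dark.base_rate,
            "hot_pixel_flat_indices": np.flatnonzero(hot_mask).tolist(),
            "generator": "dsca.synthetic_frames",
        },
    )


@dataclass
class ScenarioProfile:
    """A flow time course: alpha_db(t) with labeled segments.

    ``segments`` maps a label (e.g. "baseline", "occlusion", "release") to a
    half-open time interval (t0, t1) in seconds.
    """

    timestamps: np.ndarray
    alpha_db_series: np.ndarray
    segments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.alpha_db_series = np.asarray(self.alpha_db_series, dtype=float)
        if self.timestamps.shape != self.alpha_db_series.shape:
            raise ValueError("timestamps and alpha_db_series must match in length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.alpha_db_series < 0):
            raise ValueError("alpha_db_series must be >= 0")

    def segment_indices(self, label: str) -> np.ndarray:
        t0, t1 = self.segments[label]
        return np.flatnonzero((self.timestamps >= t0) & (self.timestamps < t1))

    @classmethod
    def cuff_occlusion(
        cls,
        frame_rate: float,
        baseline_alpha_db: float = 1e-6,
        baseline_s: float = 3.5,
        occlusion_s: float = 7.0,
        recovery_s: float = 4.0,
        occlusion_factor: float = 0.1,
        hyperemia_factor: float = 3.0,
        hyperemia_tau_s: float = 2.0,
    ) -> "ScenarioProfile":
        """Arterial cuff occlusion: baseline, deep flow drop, hyperemic overshoot.

        The cuff inflation suppresses flow to ``occlusion_factor`` of
        baseline; on release flow overshoots to ``hyperemia_factor`` times
        baseline and relaxes exponentially back with time constant
        ``hyperemia_tau_s`` (reactive hyperemia).
        """
        total = baseline_s + occlusion_s + recovery_s
        t = np.arange(0.0, total, 1.0 / frame_rate)
        a = np.full_like(t, baseline_alpha_db)
        occl = (t >= baseline_s) & (t < baseline_s + occlusion_s)
        a[occl] = baseline_alpha_db * occlusion_factor
        rel = t >= baseline_s + occlusion_s
        t_rel = t[rel] - (baseline_s + occlusion_s)
        a[rel] = baseline_alpha_db * (
            1.0 + (hyperemia_factor - 1.0) * np.exp(-t_rel / hyperemia_tau_s)
        )
        return cls(
            timestamps=t,
            alpha_db_series=a,
            segments={
                "baseline": (0.0, baseline_s),
                "occlusion": (baseline_s, baseline_s + occlusion_s),
                "release": (baseline_s + occlusion_s, total),
            },
        )

    @classmethod
    def arithmetic_task(
        cls,
        frame_rate: float,
        baseline_alpha_db: float = 1e-6,
        rest_s: float = 8.0,
        task_s: float = 30.0,
        recovery_s: float = 10.0,
        task_step_fraction: float = 0.08,
    ) -> "ScenarioProfile":
        """Cognitive activation: rest, sustained flow step during the task, recovery."""
        total = rest_s + task_s + recovery_s
        t = np.arange(0.0, total, 1.0 / frame_rate)
        a = np.full_like(t, baseline_alpha_db)
        task = (t >= rest_s) & (t < rest_s + task_s)
        a[task] = baseline_alpha_db * (1.0 + task_step_fraction)
        return cls(
            timestamps=t,
            alpha_db_series=a,
            segments={
                "baseline": (0.0, rest_s),
                "task": (rest_s, rest_s + task_s),
                "recovery": (rest_s + task_s, total),
            },
        )


def generate_scenario_stack(
    profile: ScenarioProfile,
    optics: OpticalProperties,
    geom: SemiInfiniteGeometry,
    exposure: float,
    beta: float = 1.0,
    mean_photons: float = DEFAULT_MEAN_PHOTONS,
    dark: DarkModel | None = None,
    seed: int | None = None,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    frame_rate: float | None = None,
):
    """Frame stack following a flow time course, plus its ground truth.

    Each frame's target contrast is kappa^2(alpha_db(t)) from the forward
    model (cached over the distinct flow values of the profile); frames are
    gamma-Poisson draws at that contrast and ``mean_photons``, with optional
    Poisson dark counts added.  Returns ``(stack, truth)`` where ``truth`` is
    a DataFrame with columns ``time_s, alpha_db, kappa_sq_target,
    bfi_target``.
    """
    rng = np.random.default_rng(seed)
    if frame_rate is None:
        dt = np.diff(profile.timestamps)
        frame_rate = 1.0 / float(dt[0]) if dt.size else 1.0

    alphas = profile.alpha_db_series
    cache: dict[float, float] = {}
    for a in np.unique(alphas):
        cache[float(a)] = speckle_contrast_sq(
            optics, FlowParams(alpha_db=float(a), beta=beta), geom, exposure
        )
    kappa_sq_t = np.array([cache[float(a)] for a in alphas])

    n_frames = alphas.size
    full = (n_frames,) + tuple(shape)
    m_t = 1.0 / kappa_sq_t  # per-frame gamma shape
    latent = rng.gamma(
        shape=m_t[:, None, None],
        scale=mean_photons / m_t[:, None, None],
        size=full,
    )
    counts = _poisson_counts(rng, latent)

    dark_meta: dict = {}
    if dark is not None:
        pixel_map, hot_mask = dark.realize(tuple(shape))
        counts = (counts + _poisson_counts(rng, np.broadcast_to(pixel_map, full))).astype(
            np.uint32
        )
        dark_meta = {
            "base_rate": dark.base_rate,
            "hot_pixel_flat_indices": np.flatnonzero(hot_mask).tolist(),
        }

    stack = FrameStack(
        counts=counts,
        exposure_time=exposure,
        frame_rate=frame_rate,
        rho=geom.rho,
        metadata={
            "seed": seed,
            "scenario": "profile",
            "segments": {k: list(v) for k, v in profile.segments.items()},
            "mean_photons": mean_photons,
            "generator": "dsca.synthetic_frames",
            **dark_meta,
        },
    )
    truth = pd.DataFrame(
        {
            "time_s": profile.timestamps,
            "alpha_db": alphas,
            "kappa_sq_target": kappa_sq_t,
            "bfi_target": 1.0 / kappa_sq_t,
        }
    )
    return stack, truth
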