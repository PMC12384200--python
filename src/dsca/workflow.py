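"""Top-level simulate -> process -> analyze orchestration.

A :class:`RunConfig` collects every knob of a run (tissue optics, flow,
geometry, acquisition timing, generator, pipeline and analysis settings) and
``run_pipeline`` executes the chain deterministically from a single seed,
leaving a series CSV, a JSON summary and a log on disk.  Configs load from
flat TOML blocks using field-customary units (nm, ms) and convert to the
internal mm/s convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from . import contrast_pipeline as cp
from . import signal_analysis as sa
from .forward_model import FlowParams, OpticalProperties, SemiInfiniteGeometry
from .io import write_frames, write_series
from .synthetic_frames import DarkModel, ScenarioProfile, generate_dark_frames, generate_scenario_stack

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

try:
    _VERSION = version("dsca")
except PackageNotFoundError:  # pragma: no cover - not installed
    _VERSION = "unknown"


@dataclass
class RunConfig:
    """Validated configuration for one synthetic acquisition + processing run."""

    seed: int
    # optics / flow / geometry
    mua_mm: float = 0.01
    musp_mm: float = 1.0
    n: float = 1.33
    wavelength_nm: float = 785.0
    alpha_db_mm2s: float = 1e-6
    beta: float = 1.0
    rho_mm: float = 20.0
    exposure_ms: float = 2.0
    # generator
    scenario: str = "occlusion"  # occlusion | task | constant
    frame_rate_fps: float = 50.0
    mean_photons: float = 10.0
    shape: tuple[int, int] = (128, 128)
    dark_base_rate: float = 2.0
    dark_hot_fraction: float = 0.01
    dark_hot_multiplier: float = 50.0
    n_dark_frames: int = 1000
    # pipeline
    baseline_window_s: tuple[float, float] = (0.0, 3.5)
    smoothing_window: int = 20
    bad_pixel_sigma: float = 3.0
    # analysis
    psd_segment_length: int = 256
    envelope_window: int = 250

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic step")
        if self.scenario not in ("occlusion", "task", "constant"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        # delegate physical validation to the domain types
        self.optics()
        self.flow()

    def optics(self) -> OpticalProperties:
        return OpticalProperties(
            mua=self.mua_mm, musp=self.musp_mm, n=self.n,
            wavelength=self.wavelength_nm * 1e-6,
        )

    def flow(self) -> FlowParams:
        return FlowParams(alpha_db=self.alpha_db_mm2s, beta=self.beta)

    def geometry(self) -> SemiInfiniteGeometry:
        return SemiInfiniteGeometry.for_separation(self.rho_mm, self.optics())

    def dark_model(self) -> DarkModel:
        return DarkModel(
            base_rate=self.dark_base_rate,
            hot_fraction=self.dark_hot_fraction,
            hot_multiplier=self.dark_hot_multiplier,
        )

    def profile(self) -> ScenarioProfile:
        if self.scenario == "occlusion":
            return ScenarioProfile.cuff_occlusion(
                frame_rate=self.frame_rate_fps,
                baseline_alpha_db=self.alpha_db_mm2s,
            )
        if self.scenario == "task":
            return ScenarioProfile.arithmetic_task(
                frame_rate=self.frame_rate_fps,
                baseline_alpha_db=self.alpha_db_mm2s,
            )
        # constant flow over 10 s
        t = np.arange(0.0, 10.0, 1.0 / self.frame_rate_fps)
        return ScenarioProfile(
            timestamps=t,
            alpha_db_series=np.full_like(t, self.alpha_db_mm2s),
            segments={"baseline": (0.0, 10.0)},
        )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        """Load from a flat TOML file of blocks mirroring the config fields."""
        raw = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "shape" in flat:
            flat["shape"] = tuple(flat["shape"])
        if "baseline_window_s" in flat:
            flat["baseline_window_s"] = tuple(flat["baseline_window_s"])
        return cls(**flat)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, outdir, *, save_frames: bool = False) -> dict:
    """Execute simulate -> dark calibration -> contrast -> normalize -> smooth.

    Deterministic given ``config.seed``; partial outputs are removed if a
    stage fails.  Returns a dict of artifact paths plus the in-memory
    series.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("dsca")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    profile = config.profile()
    # fail fast on an invalid baseline window, before any simulation
    t0, t1 = config.baseline_window_s
    if t0 >= profile.timestamps[-1] or t1 <= profile.timestamps[0] or t1 <= t0:
        root.removeHandler(handler)
        handler.close()
        raise ValueError(
            f"baseline window {config.baseline_window_s} outside series span "
            f"[0, {profile.timestamps[-1]:.3f}]"
        )

    try:
        simulate = _stage("simulate")(_simulate)
        stack, truth, dark_stack = simulate(config, profile)
        calibrate = _stage("dark-calibration")(_calibrate)
        dark_stats, mask = calibrate(config, dark_stack)
        process = _stage("process")(_process)
        series = process(config, stack, dark_stats, mask)

        if save_frames:
            artifacts.append(write_frames(stack, outdir / "frames.h5"))
            artifacts.append(write_frames(dark_stack, outdir / "dark.h5"))
        series_path = outdir / "series.csv"
        write_series(series, series_path)
        artifacts += [series_path, series_path.with_suffix(".json")]

        summary = {
            "package_version": _VERSION,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_frames": stack.n_frames,
            "n_flagged": mask.n_flagged,
            "n_negative_kappa_c_sq": series.attrs.get("n_negative_kappa_c_sq"),
            "baseline_bfi": series.attrs.get("baseline_bfi"),
            "baseline_window_s": list(config.baseline_window_s),
            "segment_rbfi_means": {
                label: float(np.nanmean(series.rbfi[profile.segment_indices(label)]))
                for label in profile.segments
            },
        }
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, default=str))
        artifacts.append(summary_path)
    except Exception:
        for p in artifacts:
            p.unlink(missing_ok=True)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    return {
        "series": series,
        "truth": truth,
        "series_csv": outdir / "series.csv",
        "summary_json": outdir / "summary.json",
        "log": log_path,
    }


def _simulate(config: RunConfig, profile: ScenarioProfile):
    rng = np.random.default_rng(config.seed)
    seed_scene, seed_dark = rng.integers(0, 2**31 - 1, size=2)
    stack, truth = generate_scenario_stack(
        profile,
        config.optics(),
        config.geometry(),
        exposure=config.exposure_ms * 1e-3,
        beta=config.beta,
        mean_photons=config.mean_photons,
        dark=config.dark_model(),
        seed=int(seed_scene),
        shape=config.shape,
        frame_rate=config.frame_rate_fps,
    )
    dark_stack = generate_dark_frames(
        config.dark_model(),
        n_frames=config.n_dark_frames,
        shape=config.shape,
        seed=int(seed_dark),
        exposure_time=config.exposure_ms * 1e-3,
        frame_rate=config.frame_rate_fps,
    )
    return stack, truth, dark_stack


def _calibrate(config: RunConfig, dark_stack):
    dark_stats = cp.estimate_dark_statistics(dark_stack)
    mask = cp.flag_bad_pixels(dark_stats.mean_map, n_sigma=config.bad_pixel_sigma)
    return dark_stats, mask


def _process(config: RunConfig, stack, dark_stats, mask):
    series = cp.process_stack(stack, dark_stats, mask)
    series = cp.normalize_bfi(series, config.baseline_window_s)
    return cp.smooth_series(series, config.smoothing_window)


def analyze_series(series: cp.ContrastSeries, config: RunConfig) -> dict:
    """Summary analyses of a processed series (PSD peak, SNR, trend change)."""
    fs = series.attrs.get("frame_rate_fps", config.frame_rate_fps)
    x = series.bfi[np.isfinite(series.bfi)]
    out: dict = {"snr_db": sa.series_snr_db(x)}
    if x.size >= config.psd_segment_length:
        psd = sa.welch_psd(x, fs, segment_length=config.psd_segment_length)
        out["psd_total_power"] = psd.total_power
        out["psd_peak_hz"] = psd.peak_frequency(f_min=0.1)
    if x.size > config.envelope_window:
        trend = sa.envelope_trend(x, window=config.envelope_window).trend
        change = sa.percent_change(trend, sampling_rate=fs, baseline_s=8.0)
        out["max_percent_change"] = float(np.max(change))
    return out
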