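"""Photon-counting acquisition timing for the SPAD camera.

The chip exposes two registers: TBIN_CLK_PERIODS sets the minimum exposure
unit (in clock periods) and TINT_TBIN_ITERATIONS the number of on-chip
accumulations per frame, so

    exposure = iterations * tbin_clk_periods / clock_frequency
    frame_time = exposure + readout_time
    frame_rate = 1 / frame_time

Readout time is a stored constant (global shutter, 1.1264 ms at a 20 MHz
clock); the chip gives no row-level formula for it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "TimingConfig",
    "exposure_time",
    "frame_time",
    "frame_rate",
    "timing_table",
    "TABLE_ITERATIONS",
]

MAX_ITERATIONS = 65535

#: accumulation settings printed in the sensor's published timing table
TABLE_ITERATIONS = (32, 64, 128, 256, 512, 1024, 2048, 4096)


@dataclass(frozen=True)
class TimingConfig:
    tint_tbin_iterations: int
    clock_frequency: float = 20e6  # Hz
    tbin_clk_periods: int = 32
    readout_time: float = 1.1264e-3  # s, global shutter frame readout

    def __post_init__(self) -> None:
        if not self.clock_frequency > 0:
            raise ValueError(f"clock_frequency must be > 0, got {self.clock_frequency}")
        if self.tbin_clk_periods < 1:
            raise ValueError(
                f"tbin_clk_periods must be >= 1, got {self.tbin_clk_periods}"
            )
        if not 1 <= self.tint_tbin_iterations <= MAX_ITERATIONS:
            raise ValueError(
                "tint_tbin_iterations must be in [1, 65535], "
                f"got {self.tint_tbin_iterations}"
            )
        if self.readout_time < 0:
            raise ValueError(f"readout_time must be >= 0, got {self.readout_time}")


def exposure_time(cfg: TimingConfig) -> float:
    """Exposure (integration) time in seconds."""
    return cfg.tint_tbin_iterations * cfg.tbin_clk_periods / cfg.clock_frequency


def frame_time(cfg: TimingConfig) -> float:
    """Exposure plus frame readout, seconds."""
    return exposure_time(cfg) + cfg.readout_time


def frame_rate(cfg: TimingConfig) -> float:
    """Acquisition rate, frames per second."""
    return 1.0 / frame_time(cfg)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how rates are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def timing_table(
    iterations=TABLE_ITERATIONS,
    clock_frequency: float = 20e6,
    tbin_clk_periods: int = 32,
    readout_time: float = 1.1264e-3,
) -> pd.DataFrame:
    """Exposure / frame-time / frame-rate table over accumulation settings.

    Frame rate is reported half-up to one decimal (`frame_rate_fps`) the way
    the sensor's data sheet prints it; the exact rate is kept in
    ``frame_rate_exact_fps``.
    """
    base = TimingConfig(
        tint_tbin_iterations=1,
        clock_frequency=clock_frequency,
        tbin_clk_periods=tbin_clk_periods,
        readout_time=readout_time,
    )
    rows = []
    for it in iterations:
        cfg = replace(base, tint_tbin_iterations=int(it))
        rate = frame_rate(cfg)
        rows.append(
            {
                "tint_tbin_iterations": int(it),
                "exposure_s": exposure_time(cfg),
                "frame_readout_s": cfg.readout_time,
                "frame_time_s": frame_time(cfg),
                "frame_rate_fps": round_half_up(rate, 1),
                "frame_rate_exact_fps": rate,
            }
        )
    return pd.DataFrame(rows)
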