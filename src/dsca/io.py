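"""Frame-container and time-series I/O.

Canonical frame container is HDF5: dataset ``/frames`` (unsigned integers,
frames x rows x cols) with attributes ``exposure_s``, ``frame_rate_fps``,
``rho_mm`` and a ``metadata`` JSON string.  Multi-page TIFF is supported as
an interchange format (metadata in the image description tag).  1-D series
travel as CSV with an optional JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .contrast_pipeline import ContrastSeries
from .synthetic_frames import FrameStack

__all__ = [
    "write_frames",
    "read_frames",
    "write_frames_tiff",
    "read_frames_tiff",
    "write_series",
    "read_series",
]

_REQUIRED_ATTRS = ("exposure_s", "frame_rate_fps", "rho_mm")


def write_frames(stack: FrameStack, path) -> Path:
    """Write a frame stack to HDF5; round-trips exactly through read_frames."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(
            "frames", data=stack.counts.astype(np.uint32), compression="gzip"
        )
        ds.attrs["exposure_s"] = stack.exposure_time
        ds.attrs["frame_rate_fps"] = stack.frame_rate
        ds.attrs["rho_mm"] = stack.rho
        ds.attrs["metadata"] = json.dumps(stack.metadata)
    return path


def read_frames(path) -> FrameStack:
    """Read an HDF5 frame container written by :func:`write_frames`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise KeyError(f"{path}: missing dataset 'frames'")
        ds = f["frames"]
        for key in _REQUIRED_ATTRS:
            if key not in ds.attrs:
                raise KeyError(f"{path}: missing attribute '{key}'")
        metadata = json.loads(ds.attrs.get("metadata", "{}"))
        return FrameStack(
            counts=ds[...],
            exposure_time=float(ds.attrs["exposure_s"]),
            frame_rate=float(ds.attrs["frame_rate_fps"]),
            rho=float(ds.attrs["rho_mm"]),
            metadata=metadata,
        )


def write_frames_tiff(stack: FrameStack, path) -> Path:
    """Write a multi-page TIFF; acquisition metadata goes in the description."""
    path = Path(path)
    desc = json.dumps(
        {
            "exposure_s": stack.exposure_time,
            "frame_rate_fps": stack.frame_rate,
            "rho_mm": stack.rho,
            "metadata": stack.metadata,
        }
    )
    tifffile.imwrite(path, stack.counts.astype(np.uint32), description=desc)
    return path


def read_frames_tiff(path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_frames_tiff`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        counts = tf.asarray()
        desc = tf.pages[0].description
    try:
        info = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise KeyError(f"{path}: missing or invalid description metadata") from exc
    for key in _REQUIRED_ATTRS:
        if key not in info:
            raise KeyError(f"{path}: missing attribute '{key}'")
    if counts.ndim == 2:
        counts = counts[None]
    return FrameStack(
        counts=counts,
        exposure_time=float(info["exposure_s"]),
        frame_rate=float(info["frame_rate_fps"]),
        rho=float(info["rho_mm"]),
        metadata=info.get("metadata", {}),
    )


def write_series(series: ContrastSeries, path, sidecar: dict | None = None) -> Path:
    """Write a contrast series to CSV with a JSON sidecar of its attrs."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    side = dict(series.attrs)
    if sidecar:
        side.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(side, indent=2, default=str))
    return path


def read_series(path) -> ContrastSeries:
    """Read a contrast-series CSV (and its JSON sidecar if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    attrs = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        attrs = json.loads(sidecar.read_text())
    return ContrastSeries.from_frame(df, attrs=attrs)
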