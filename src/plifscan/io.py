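"""Standard-format I/O: TIFF frame stacks, CSV sidecars, volume export, manifests.

Frame stacks are multi-page grayscale TIFF (16-bit raw input, 32-bit float
intermediates) with a CSV sidecar whose mandatory header is
``frame_index,timestamp_s,position_mm``.  Volumes are z'-ordered 32-bit float
multi-page TIFF plus a JSON metadata sidecar (spacing, origin, window, the
NaN missing-voxel sentinel).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import RawFrame
from .reconstruct import FrameSequence, VoxelVolume

__all__ = [
    "SIDECAR_COLUMNS",
    "write_frame_stack",
    "read_frame_stack",
    "write_volume",
    "read_volume",
    "RunManifest",
]

SIDECAR_COLUMNS = ("frame_index", "timestamp_s", "position_mm")


def write_frame_stack(path, frames, sidecar_path=None, dtype=None) -> None:
    """Write frames (RawFrame list or 3D array) as a multi-page TIFF.

    Integer-valued stacks are stored as uint16, everything else as float32.
    A sidecar CSV with timestamps/positions is written when ``sidecar_path``
    is given and frames carry metadata.
    """
    if isinstance(frames, FrameSequence):
        arrays = list(frames.frames)
        times, pos = frames.timestamps_s, frames.positions_mm
    elif frames and isinstance(frames[0], RawFrame):
        arrays = [f.intensities for f in frames]
        times = [f.timestamp_s for f in frames]
        pos = [f.position_mm for f in frames]
    else:
        arrays = [np.asarray(f) for f in frames]
        times = pos = None
    stack = np.stack(arrays)
    if dtype is None:
        integral = np.all(stack == np.rint(stack)) and stack.min() >= 0 and stack.max() <= 65535
        dtype = np.uint16 if integral else np.float32
    tifffile.imwrite(path, stack.astype(dtype), photometric="minisblack")
    if sidecar_path is not None:
        if times is None:
            raise ValueError("frames carry no timestamps/positions for a sidecar")
        pd.DataFrame(
            {
                "frame_index": np.arange(len(arrays)),
                "timestamp_s": np.asarray(times, dtype=float),
                "position_mm": np.asarray(pos, dtype=float),
            }
        ).to_csv(sidecar_path, index=False)


def read_frame_stack(path, sidecar_path=None) -> list[RawFrame]:
    """Read a multi-page TIFF stack with optional CSV sidecar metadata."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a stack of 2D frames, got shape {stack.shape}")
    if stack.shape[1] != stack.shape[2]:
        raise ValueError(f"frames must be square, got {stack.shape[1]}x{stack.shape[2]}")
    n = len(stack)
    if sidecar_path is not None:
        table = pd.read_csv(sidecar_path)
        missing = set(SIDECAR_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"sidecar {sidecar_path} lacks columns {sorted(missing)}")
        if len(table) != n:
            raise ValueError(
                f"stack has {n} pages but sidecar has {len(table)} rows"
            )
        times = table["timestamp_s"].to_numpy(float)
        pos = table["position_mm"].to_numpy(float)
    else:
        times = np.arange(n, dtype=float)
        pos = np.zeros(n)
    return [
        RawFrame(frame.astype(float), timestamp_s=t, position_mm=p)
        for frame, t, p in zip(stack, times, pos)
    ]


def frames_to_sequence(frames: list[RawFrame]) -> FrameSequence:
    return FrameSequence(
        frames=np.stack([f.intensities for f in frames]),
        positions_mm=np.array([f.position_mm for f in frames]),
        timestamps_s=np.array([f.timestamp_s for f in frames]),
    )


def write_volume(prefix, volume: VoxelVolume) -> tuple[Path, Path]:
    """Write a voxel volume as z'-ordered float32 TIFF + JSON metadata."""
    prefix = Path(prefix)
    tif = prefix.with_suffix(".tif")
    meta = prefix.with_suffix(".json")
    pages = np.transpose(volume.values, (2, 1, 0)).astype(np.float32)  # (z, y, x)
    tifffile.imwrite(tif, pages, photometric="minisblack")
    with open(meta, "w") as fh:
        json.dump(
            {
                "axes": "pages are z'; page rows are y; page columns are x'",
                "spacing_mm": list(volume.spacing_mm),
                "origin_mm": list(volume.origin_mm),
                "window_s": list(volume.window_s),
                "missing_sentinel": "NaN",
                "shape_xyz": list(volume.values.shape),
            },
            fh,
            indent=2,
        )
    return tif, meta


def read_volume(prefix) -> VoxelVolume:
    prefix = Path(prefix)
    pages = tifffile.imread(prefix.with_suffix(".tif")).astype(float)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return VoxelVolume(
        values=np.transpose(pages, (2, 1, 0)),
        spacing_mm=tuple(meta["spacing_mm"]),
        origin_mm=tuple(meta["origin_mm"]),
        window_s=tuple(meta["window_s"]),
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    config: dict
    parameters: dict
    input_digests: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    software_version: str = ""
    created_utc: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__

            self.software_version = __version__
        if not self.created_utc:
            self.created_utc = datetime.now(timezone.utc).isoformat()

    @classmethod
    def build(cls, config, parameters: dict, inputs: dict | None = None,
              seeds: dict | None = None) -> "RunManifest":
        digests = {name: _digest(p) for name, p in (inputs or {}).items()}
        cfg = config.to_dict() if hasattr(config, "to_dict") else dict(config)
        return cls(config=cfg, parameters=parameters, input_digests=digests,
                   seeds=seeds or {})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
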