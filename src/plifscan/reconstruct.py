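"""Assembly of corrected frames into time-windowed 3D voxel volumes.

Each corrected frame samples concentration on an oblique sheet; the shear
``(m, n, p) -> (m c, n, p + m c)`` places its pixels in chamber coordinates.
Because every column ``j`` of every frame lands on the same regular x' lattice
(spacing ``dy * cos(theta)``), assembly reduces to dropping whole pixel
columns into z' voxels: nearest-voxel assignment with averaging of
multiply-hit voxels.  Voxels never intersected by any sheet carry NaN, which
is distinct from a measured zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import SystemConfig, binned_pixel_size, derive_resolution

__all__ = [
    "FrameSequence",
    "VoxelVolume",
    "window_frames",
    "place_frame",
    "reconstruct_volume",
    "sweep_direction_merge",
    "volume_grid",
]

logger = logging.getLogger(__name__)

MISSING = np.nan


@dataclass
class FrameSequence:
    """Ordered corrected frames with per-frame sheet positions and timestamps."""

    frames: np.ndarray  # (n_frames, ny, nx)
    positions_mm: np.ndarray
    timestamps_s: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        n = len(self.frames)
        if len(self.positions_mm) != n or len(self.timestamps_s) != n:
            raise ValueError(
                f"lengths disagree: {n} frames, {len(self.positions_mm)} positions, "
                f"{len(self.timestamps_s)} timestamps"
            )
        if n > 1 and np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class VoxelVolume:
    """Reconstructed relative-concentration grid.

    ``values[ix, iy, iz]`` with axes (x', y, z'); ``spacing`` is
    (dx', dy, dz) in mm, ``origin`` the chamber coordinate of voxel [0,0,0],
    and untouched voxels hold NaN.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    window_s: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("voxel volume must be 3D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        measured = self.values[np.isfinite(self.values)]
        if measured.size and np.any(measured < -1e-9):
            raise ValueError("measured voxel values must be >= 0")

    @property
    def measured_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def centroid_mm(self) -> np.ndarray:
        """Intensity-weighted centroid of measured voxels, chamber coords."""
        mask = self.measured_mask
        w = np.where(mask, self.values, 0.0)
        total = w.sum()
        if total <= 0:
            return np.full(3, np.nan)
        idx = np.indices(self.values.shape, dtype=float)
        return np.array([
            (idx[a] * w).sum() / total * self.spacing_mm[a] + self.origin_mm[a]
            for a in range(3)
        ])


def window_frames(
    seq: FrameSequence,
    window_duration_s: float,
    frame_rate_hz: float | None = None,
) -> list[FrameSequence]:
    """Partition a sequence into consecutive fixed-duration windows.

    Window size is ``round(frame_rate * duration)`` frames; a trailing partial
    window is dropped with a logged warning.
    """
    if window_duration_s <= 0:
        raise ValueError("window_duration_s must be > 0")
    if frame_rate_hz is None:
        if len(seq) < 2:
            raise ValueError("cannot infer frame rate from fewer than 2 frames")
        frame_rate_hz = 1.0 / float(np.median(np.diff(seq.timestamps_s)))
    size = round(frame_rate_hz * window_duration_s)
    if size < 1:
        raise ValueError("window shorter than one frame interval")
    n_windows = len(seq) // size
    if n_windows == 0:
        raise ValueError(
            f"sequence of {len(seq)} frames is shorter than one "
            f"{size}-frame window"
        )
    dropped = len(seq) - n_windows * size
    if dropped:
        logger.warning("dropping %d trailing frames that do not fill a window", dropped)
    out = []
    for k in range(n_windows):
        sl = slice(k * size, (k + 1) * size)
        out.append(FrameSequence(seq.frames[sl], seq.positions_mm[sl], seq.timestamps_s[sl]))
    return out


def place_frame(frame: np.ndarray, p: float, config: SystemConfig):
    """Chamber-coordinate samples of one corrected frame at sheet position p.

    Returns ``(x', y, z', values)`` arrays where ``x'`` and ``z'`` are per
    column and ``y`` per row; values are carried unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = 0.0, max(config.chamber_dims_mm)
    if not (lo <= p <= hi):
        raise ValueError(f"sheet position {p} mm outside the chamber scan range")
    dy = config.imaging_plane_extent_mm / frame.shape[1]
    c = config.plane_wall_cos
    m = np.arange(frame.shape[1], dtype=float) * dy
    n = np.arange(frame.shape[0], dtype=float) * dy
    x = m * c
    z = p + m * c
    return x, n, z, frame


def volume_grid(positions_mm: np.ndarray, frame_shape: tuple[int, int],
                config: SystemConfig):
    """Regular (x', y, z') voxel grid covering a window's sheet positions.

    Shared between reconstruction and the simulator's ground-truth sampler so
    both live on identical lattices.
    """
    ny, nx = frame_shape
    dy = config.imaging_plane_extent_mm / nx
    c = config.plane_wall_cos
    dxp = dy * c
    dz = config.platform_speed_mm_s / config.frame_rate_hz
    if dz <= 0:  # stationary platform: single-slice spacing fallback
        dz = dxp
    p = np.asarray(positions_mm, dtype=float)
    z0 = float(p.min())
    zmax = float(p.max()) + (nx - 1) * dxp
    nz = int(np.floor((zmax - z0) / dz + 0.5)) + 1
    xs = np.arange(nx) * dxp
    ys = np.arange(ny) * dy
    zs = z0 + np.arange(nz) * dz
    return xs, ys, zs


def reconstruct_volume(
    window: FrameSequence,
    config: SystemConfig,
    interpolate_z: bool = False,
) -> VoxelVolume:
    """Resample one window of sheared frames onto a regular voxel grid.

    The x' lattice after the shear is already regular (spacing dy cos(theta))
    so only z' needs assignment: nearest voxel, averaging multiply-hit voxels.
    With ``interpolate_z`` the two neighbouring z voxels are weighted linearly
    instead.
    """
    if len(window) == 0:
        raise ValueError("empty frame window")
    pos = window.positions_mm
    if len(window) > 1 and np.allclose(pos, pos[0]):
        warnings.warn(
            "stationary platform: reconstruction degenerates to a single-slice volume",
            stacklevel=2,
        )
    order = np.argsort(pos, kind="stable")
    frames = window.frames[order]
    pos = pos[order]
    ny, nx = frames.shape[1:]
    xs, ys, zs = volume_grid(pos, (ny, nx), config)
    dz = zs[1] - zs[0] if len(zs) > 1 else 1.0
    dxp = xs[1] - xs[0] if len(xs) > 1 else 1.0
    dy = ys[1] - ys[0] if len(ys) > 1 else 1.0

    sums = np.zeros((nx, ny, len(zs)))
    counts = np.zeros((nx, len(zs)))
    cols = np.arange(nx)
    mprime = cols * dxp
    for f, p in zip(frames, pos):
        zc = p + mprime  # z' of each column
        if interpolate_z:
            frac = (zc - zs[0]) / dz
            i0 = np.clip(np.floor(frac).astype(int), 0, len(zs) - 1)
            i1 = np.clip(i0 + 1, 0, len(zs) - 1)
            w1 = np.clip(frac - i0, 0.0, 1.0)
            sums[cols, :, i0] += (f * (1 - w1)[None, :]).T
            sums[cols, :, i1] += (f * w1[None, :]).T
            counts[cols, i0] += 1 - w1
            counts[cols, i1] += w1
        else:
            iz = np.clip(np.rint((zc - zs[0]) / dz).astype(int), 0, len(zs) - 1)
            sums[cols, :, iz] += f.T
            counts[cols, iz] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / counts[:, None, :]
    values[counts[:, None, :].repeat(ny, axis=1) == 0] = MISSING
    return VoxelVolume(
        values=values,
        spacing_mm=(dxp, dy, dz),
        origin_mm=(0.0, 0.0, float(zs[0])),
        window_s=(float(window.timestamps_s[0]), float(window.timestamps_s[-1])),
    )


def sweep_direction_merge(sequences: list[FrameSequence]) -> FrameSequence:
    """Concatenate per-sweep sequences (forward and reverse) chronologically.

    Frames from either sweep direction are equally usable; within a window
    the reconstruction sorts by position.  Input sequences must already be
    time-ordered and mutually chronological.
    """
    if not sequences:
        raise ValueError("no sequences to merge")
    last_t = -np.inf
    for s in sequences:
        if s.timestamps_s[0] <= last_t:
            raise ValueError("sequences are not in chronological order")
        last_t = s.timestamps_s[-1]
    return FrameSequence(
        frames=np.concatenate([s.frames for s in sequences]),
        positions_mm=np.concatenate([s.positions_mm for s in sequences]),
        timestamps_s=np.concatenate([s.timestamps_s for s in sequences]),
    )
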