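"""Instrument geometry, kinematics, and coordinate transforms.

The scanned-PLIF rig is a continuous-wave laser shaped into a fan-beam sheet,
imaged by a square sCMOS sensor, both riding a platform that translates along
the chamber's long (Z) axis.  The laser sheet sits at a fixed angle to the
chamber sidewall, so in-sheet pixel coordinates must be sheared into chamber
coordinates before frames can be stacked into a volume.

Conventions
-----------
* ``m`` runs along the sheet away from the laser origin, ``n`` runs vertically;
  both are physical offsets in mm of (binned) pixel centers from the origin
  pixel center.  The origin pixel is the corner nearest the laser source,
  where illumination is strongest.
* ``p`` is the recorded sheet-origin position of a frame along the scan axis.
* The shear maps ``(m, n, p)`` to chamber coordinates
  ``(m', n', p') = (m cos(theta), n, p + m cos(theta))`` where ``theta`` is the
  sheet/wall angle; at the standard 45 degrees both factors are ``1/sqrt(2)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SystemConfig",
    "PlatformTrajectory",
    "ResolutionReport",
    "binned_pixel_size",
    "derive_resolution",
    "transform_coordinates",
    "inverse_transform_coordinates",
    "frame_positions",
]


class ConfigurationError(ValueError):
    """Raised when instrument configuration fields are inconsistent."""


def _default_r0(fan_angle_deg: float, plane_extent_mm: float) -> float:
    # Distance from the fan apex at which the fan just spans the imaging
    # plane width: half-width / tan(half fan angle).
    half = math.radians(fan_angle_deg / 2.0)
    return plane_extent_mm / 2.0 / math.tan(half)


@dataclass(frozen=True)
class SystemConfig:
    """Full instrument geometry and kinematics.

    All lengths in mm, rates in Hz, speeds in mm/s, angles in degrees.
    ``r0_mm`` is the laser-origin-to-image-origin distance along the sheet;
    it is not a measured quantity of the rig and defaults to the distance at
    which a 60 degree fan spans the 420 mm imaging plane (~363.7 mm).
    """

    fan_angle_deg: float = 60.0
    plane_wall_angle_deg: float = 45.0
    laser_wavelength_nm: float = 450.0
    laser_power_mw: float = 100.0
    frame_rate_hz: float = 12.0
    exposure_ms: float = 25.0
    sensor_pixels: int = 2048
    bin_factor: int = 4
    imaging_plane_extent_mm: float = 420.0
    imaging_distance_mm: float = 300.0
    chamber_dims_mm: tuple[float, float, float] = (500.0, 500.0, 1000.0)
    platform_speed_mm_s: float = 100.0
    scan_length_mm: float = 500.0
    emission_band_nm: tuple[float, float] = (500.0, 600.0)
    r0_mm: float | None = None

    def __post_init__(self) -> None:
        positive = {
            "laser_wavelength_nm": self.laser_wavelength_nm,
            "laser_power_mw": self.laser_power_mw,
            "frame_rate_hz": self.frame_rate_hz,
            "exposure_ms": self.exposure_ms,
            "imaging_plane_extent_mm": self.imaging_plane_extent_mm,
            "imaging_distance_mm": self.imaging_distance_mm,
            "scan_length_mm": self.scan_length_mm,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be > 0, got {value!r}")
        if self.platform_speed_mm_s < 0:
            raise ConfigurationError("platform_speed_mm_s must be >= 0")
        if not (0.0 < self.fan_angle_deg <= 90.0):
            raise ConfigurationError("fan_angle_deg must lie in (0, 90]")
        if not (0.0 < self.plane_wall_angle_deg <= 90.0):
            raise ConfigurationError("plane_wall_angle_deg must lie in (0, 90]")
        if self.sensor_pixels <= 0 or self.bin_factor <= 0:
            raise ConfigurationError("sensor_pixels and bin_factor must be positive")
        if self.sensor_pixels % self.bin_factor != 0:
            raise ConfigurationError(
                f"sensor_pixels ({self.sensor_pixels}) not divisible by "
                f"bin_factor ({self.bin_factor})"
            )
        if any(d <= 0 for d in self.chamber_dims_mm):
            raise ConfigurationError("chamber dimensions must be positive")
        if self.scan_length_mm > max(self.chamber_dims_mm):
            raise ConfigurationError(
                "scan_length_mm exceeds the chamber's long axis "
                f"({self.scan_length_mm} > {max(self.chamber_dims_mm)})"
            )
        if self.r0_mm is None:
            object.__setattr__(
                self,
                "r0_mm",
                _default_r0(self.fan_angle_deg, self.imaging_plane_extent_mm),
            )
        if not self.r0_mm > 0:
            raise ConfigurationError("r0_mm must be > 0")

    # -- derived scalars ---------------------------------------------------

    @property
    def binned_pixels(self) -> int:
        return self.sensor_pixels // self.bin_factor

    @property
    def sensor_pixel_size_mm(self) -> float:
        return self.imaging_plane_extent_mm / self.sensor_pixels

    @property
    def plane_wall_cos(self) -> float:
        return math.cos(math.radians(self.plane_wall_angle_deg))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chamber_dims_mm"] = list(self.chamber_dims_mm)
        d["emission_band_nm"] = list(self.emission_band_nm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConfig":
        d = dict(d)
        if "chamber_dims_mm" in d:
            d["chamber_dims_mm"] = tuple(d["chamber_dims_mm"])
        if "emission_band_nm" in d:
            d["emission_band_nm"] = tuple(d["emission_band_nm"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SystemConfig":
        """Load from a flat YAML/JSON key-value file (units as in field names)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"configuration file {path} is not a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class PlatformTrajectory:
    """Back-and-forth motion of the sliding platform along the scan axis."""

    start_position_mm: float = 0.0
    speed_mm_s: float = 100.0
    direction: int = 1
    turnaround_low_mm: float = 0.0
    turnaround_high_mm: float = 500.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ConfigurationError("direction must be +1 or -1")
        if not self.turnaround_low_mm < self.turnaround_high_mm:
            raise ConfigurationError("turnaround_low must be < turnaround_high")
        if self.speed_mm_s < 0:
            raise ConfigurationError("speed_mm_s must be >= 0")
        lo, hi = self.turnaround_low_mm, self.turnaround_high_mm
        if not (lo <= self.start_position_mm <= hi):
            raise ConfigurationError("start_position must lie within the track")

    def position_at(self, t: float | np.ndarray) -> np.ndarray:
        """Platform position at time(s) ``t`` with reflective fold-back."""
        lo, hi = self.turnaround_low_mm, self.turnaround_high_mm
        raw = self.start_position_mm + self.direction * self.speed_mm_s * np.asarray(t, dtype=float)
        span = hi - lo
        y = np.mod(raw - lo, 2.0 * span)
        folded = np.where(y <= span, y, 2.0 * span - y)
        return lo + folded


@dataclass(frozen=True)
class ResolutionReport:
    """Voxel spacings and extents of the reconstructed volume."""

    dx_prime_mm: float
    dy_mm: float
    dz_mm: float
    volume_extent_mm: tuple[float, float, float]
    frames_per_window: int
    window_duration_s: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_extent_mm"] = list(self.volume_extent_mm)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:  # human-readable geometry report
        ex, ey, ez = self.volume_extent_mm
        return (
            "Reconstruction geometry\n"
            f"  voxel spacing : {self.dx_prime_mm:.3f} x {self.dy_mm:.3f} x "
            f"{self.dz_mm:.3f} mm (x', y, z')\n"
            f"  volume extent : {ex:.1f} x {ey:.1f} x {ez:.1f} mm (scan, x', y)\n"
            f"  time window   : {self.window_duration_s:g} s "
            f"({self.frames_per_window} frames)"
        )


def binned_pixel_size(config: SystemConfig) -> float:
    """In-plane size of one binned pixel in mm (imaging extent / binned side)."""
    return config.imaging_plane_extent_mm / config.binned_pixels


def derive_resolution(config: SystemConfig, window_duration_s: float = 5.0) -> ResolutionReport:
    """Voxel spacings/extents for the given scan configuration.

    dy is the binned in-plane pixel; dx' is its projection through the
    sheet/wall angle; dz is the platform advance per frame.  A 90 degree
    sheet/wall angle collapses the projection and is rejected.
    """
    if window_duration_s <= 0:
        raise ValueError("window_duration_s must be > 0")
    if config.plane_wall_angle_deg >= 90.0:
        raise ConfigurationError(
            "plane_wall_angle of 90 degrees collapses the x' projection; "
            "the shear is degenerate"
        )
    dy = binned_pixel_size(config)
    c = config.plane_wall_cos
    dz = config.platform_speed_mm_s / config.frame_rate_hz
    frames = round(config.frame_rate_hz * window_duration_s)
    extent = (
        config.scan_length_mm,
        config.imaging_plane_extent_mm * c,
        config.imaging_plane_extent_mm,
    )
    return ResolutionReport(
        dx_prime_mm=dy * c,
        dy_mm=dy,
        dz_mm=dz,
        volume_extent_mm=extent,
        frames_per_window=frames,
        window_duration_s=window_duration_s,
    )


def _shear_cos(plane_wall_angle_deg: float) -> float:
    if not (0.0 < plane_wall_angle_deg < 90.0):
        raise ValueError(
            "plane_wall_angle must lie in (0, 90) degrees for the shear; "
            f"got {plane_wall_angle_deg}"
        )
    return math.cos(math.radians(plane_wall_angle_deg))


def transform_coordinates(m, n, p, plane_wall_angle_deg: float = 45.0):
    """Shear in-sheet coordinates into chamber coordinates.

    Returns ``(m', n', p') = (m c, n, p + m c)`` with ``c = cos(theta)``;
    at 45 degrees this is ``(m/sqrt(2), n, p + m/sqrt(2))``.  ``m`` and ``p``
    must share a length unit; ``n`` is preserved exactly.
    """
    c = _shear_cos(plane_wall_angle_deg)
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p)) and np.all(np.isfinite(np.asarray(n, dtype=float)))):
        raise ValueError("coordinates must be finite")
    mp = m * c
    return mp, np.asarray(n), p + mp


def inverse_transform_coordinates(m_prime, n_prime, p_prime, plane_wall_angle_deg: float = 45.0):
    """Invert :func:`transform_coordinates`."""
    c = _shear_cos(plane_wall_angle_deg)
    m_prime = np.asarray(m_prime, dtype=float)
    p_prime = np.asarray(p_prime, dtype=float)
    return m_prime / c, np.asarray(n_prime), p_prime - m_prime


def frame_positions(
    trajectory: PlatformTrajectory,
    n_frames: int,
    frame_rate_hz: float,
) -> np.ndarray:
    """Sheet position of each frame for a uniformly sampled scan.

    Positions advance by ``speed / frame_rate`` per frame and reflect at the
    turnaround points (the platform folds back rather than wrapping).  A zero
    speed yields a stationary stack of identical positions.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    t = np.arange(n_frames) / frame_rate_hz
    return trajectory.position_at(t)
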