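"""Fan-beam illumination correction.

A fan-shaped laser sheet spreads its power over arcs whose length grows with
distance from the fan origin, so local sheet irradiance falls off as 1/r.
Relative to the origin pixel (the corner nearest the laser, distance r0 along
the sheet), the illumination at a pixel offset ``(m, n)`` mm is

    P(m, n) = r0 / sqrt((r0 + m)^2 + n^2)   in (0, 1]

Dividing a measured frame by P makes pixel intensity proportional to local
fluorophore concentration regardless of distance from the laser origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SystemConfig, binned_pixel_size

__all__ = ["CorrectionMap", "correction_ratio", "build_map", "apply_correction"]


def correction_ratio(m, n, r0: float):
    """Relative illumination r0 / sqrt((r0+m)^2 + n^2).

    ``m`` (along the sheet, away from the laser) and ``n`` (vertical) are
    physical offsets in mm from the origin pixel center; ``r0`` is the
    laser-origin-to-image-origin distance in the same unit.
    """
    if r0 <= 0:
        raise ValueError(f"r0 must be > 0, got {r0}")
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(m < 0):
        raise ValueError("m must be >= 0 (m increases away from the laser)")
    out = r0 / np.sqrt((r0 + m) ** 2 + n**2)
    return out if out.ndim else float(out)


@dataclass
class CorrectionMap:
    """Per-pixel relative illumination on the binned image lattice.

    ``ratios[i, j]`` is P at vertical offset ``i * pixel_size`` and along-sheet
    offset ``j * pixel_size``; the origin pixel ``[0, 0]`` (corner nearest the
    laser) has ratio exactly 1.
    """

    ratios: np.ndarray
    r0_mm: float
    pixel_size_mm: float
    origin: str = "corner nearest laser"

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2:
            raise ValueError("correction map must be 2D")
        if not np.isclose(self.ratios[0, 0], 1.0):
            raise ValueError("origin pixel of a correction map must be 1")
        if np.any(self.ratios <= 0) or np.any(self.ratios > 1 + 1e-12):
            raise ValueError("correction ratios must lie in (0, 1]")


def build_map(config: SystemConfig, shape: tuple[int, int] | None = None,
              pixel_size_mm: float | None = None) -> CorrectionMap:
    """Evaluate the correction ratio at every (binned) pixel center.

    By default the lattice is the binned sensor; pass ``shape``/``pixel_size_mm``
    to build a map for another lattice (e.g. the raw sensor grid).
    """
    if shape is None:
        side = config.binned_pixels
        shape = (side, side)
    if pixel_size_mm is None:
        pixel_size_mm = config.imaging_plane_extent_mm / shape[1] \
            if shape[1] != config.binned_pixels else binned_pixel_size(config)
    n = np.arange(shape[0], dtype=float)[:, None] * pixel_size_mm
    m = np.arange(shape[1], dtype=float)[None, :] * pixel_size_mm
    ratios = correction_ratio(m, n, config.r0_mm)
    return CorrectionMap(ratios=ratios, r0_mm=config.r0_mm, pixel_size_mm=pixel_size_mm)


def apply_correction(image: np.ndarray, cmap: CorrectionMap) -> np.ndarray:
    """Flat-field a frame: divide by the relative illumination.

    Pixels far from the laser origin receive less light and are amplified by
    1/P so intensity tracks concentration alone.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != cmap.ratios.shape:
        raise ValueError(
            f"image shape {image.shape} does not match correction map "
            f"shape {cmap.ratios.shape}"
        )
    return image / cmap.ratios
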