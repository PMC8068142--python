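"""Frame preprocessing: background subtraction, pixel binning, wavelet denoising.

The fixed stage order is background subtraction -> binning -> wavelet
soft-threshold denoising.  The threshold rule is the universal-style
construction

    delta = sigma * (0.3936 + 0.1829 * log2(N))      for N > 32, else 0

with the robust noise scale

    sigma = median(|f_i|) / 0.6745

estimated once from the finest-scale diagonal detail coefficients and reused
for every detail subband; ``N`` is the per-subband coefficient count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "RawFrame",
    "BackgroundModel",
    "WaveletParams",
    "subtract_background",
    "bin_pixels",
    "noise_sigma",
    "threshold_delta",
    "soft_threshold",
    "denoise_wavelet",
    "preprocess_frame",
]

#: slope/intercept of the threshold rule delta = sigma*(a + b*log2 N)
_DELTA_INTERCEPT = 0.3936
_DELTA_SLOPE = 0.1829
#: MAD-to-sigma conversion for a zero-mean Gaussian
_MAD_SCALE = 0.6745
#: below this coefficient count the threshold is defined as zero
_MIN_SUBBAND = 32


@dataclass
class RawFrame:
    """A single camera frame with its acquisition metadata."""

    intensities: np.ndarray
    timestamp_s: float = 0.0
    position_mm: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("frame intensities must be a 2D array")
        if self.intensities.shape[0] != self.intensities.shape[1]:
            raise ValueError(
                f"frame must be square, got shape {self.intensities.shape}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("frame intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class BackgroundModel:
    """Pixelwise mean of laser-on frames recorded before aerosol injection."""

    mean_frame: np.ndarray
    n_source_frames: int

    def __post_init__(self) -> None:
        self.mean_frame = np.asarray(self.mean_frame, dtype=float)
        if np.any(self.mean_frame < 0):
            raise ValueError("background must be non-negative")
        if self.n_source_frames < 1:
            raise ValueError("background needs at least one source frame")

    @classmethod
    def from_frames(cls, frames) -> "BackgroundModel":
        arrays = [f.intensities if isinstance(f, RawFrame) else np.asarray(f, float) for f in frames]
        if not arrays:
            raise ValueError("no background frames given")
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"background frames disagree in shape: {shapes}")
        return cls(mean_frame=np.mean(arrays, axis=0), n_source_frames=len(arrays))


@dataclass
class WaveletParams:
    """Wavelet denoising configuration.

    The default family is an orthogonal, compactly supported Daubechies
    wavelet of low order with symmetric boundary extension; both family and
    depth are free parameters of the stage.  ``levels=None`` resolves to
    4 levels or the decomposable depth of the image, whichever is smaller;
    an explicit depth beyond the decomposable limit is an error.
    """

    family: str = "db4"
    levels: int | None = None
    mode: str = "symmetric"

    def resolve_levels(self, side: int) -> int:
        max_levels = pywt.dwtn_max_level((side, side), pywt.Wavelet(self.family))
        if self.levels is None:
            return max(min(4, max_levels), 1)
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.levels > max_levels:
            raise ValueError(
                f"{self.levels} levels exceed the decomposable depth "
                f"{max_levels} for a {side}x{side} image with {self.family}"
            )
        return self.levels


def subtract_background(frame: RawFrame, bg: BackgroundModel) -> RawFrame:
    """Subtract the background model, clipping negatives to zero.

    Fluorescence counts cannot be negative, so pixels where the background
    exceeds the frame are clipped rather than left negative.
    """
    if frame.intensities.shape != bg.mean_frame.shape:
        raise ValueError(
            f"frame shape {frame.intensities.shape} does not match "
            f"background shape {bg.mean_frame.shape}"
        )
    out = np.maximum(frame.intensities - bg.mean_frame, 0.0)
    return RawFrame(out, timestamp_s=frame.timestamp_s, position_mm=frame.position_mm)


def bin_pixels(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean binning: each output pixel averages a factor x factor block.

    The mean (not sum) keeps corrected intensities on the sensor count scale
    regardless of bin factor.
    """
    image = np.asarray(image, dtype=float)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    h, w = image.shape
    if h % factor or w % factor:
        raise ValueError(
            f"image shape {image.shape} not divisible by bin factor {factor}"
        )
    return image.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def noise_sigma(detail_coeffs: np.ndarray) -> float:
    """Robust noise scale: median absolute coefficient / 0.6745."""
    c = np.ravel(np.asarray(detail_coeffs, dtype=float))
    if c.size == 0:
        raise ValueError("cannot estimate noise from an empty coefficient vector")
    return float(np.median(np.abs(c)) / _MAD_SCALE)


def threshold_delta(sigma: float, n: int) -> float:
    """Universal-style threshold delta = sigma*(0.3936 + 0.1829 log2 N).

    Defined as zero for subbands of 32 coefficients or fewer.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 0:
        raise ValueError("N must be >= 0")
    if n <= _MIN_SUBBAND:
        return 0.0
    return float(sigma * (_DELTA_INTERCEPT + _DELTA_SLOPE * math.log2(n)))


def soft_threshold(w, delta: float):
    """Sign-preserving shrinkage: sgn(w)(|w|-delta) above delta, else 0."""
    if delta < 0:
        raise ValueError("threshold delta must be >= 0")
    w = np.asarray(w, dtype=float)
    out = np.sign(w) * np.maximum(np.abs(w) - delta, 0.0)
    return out if out.ndim else float(out)


def denoise_wavelet(image: np.ndarray, params: WaveletParams | None = None) -> np.ndarray:
    """Soft-threshold wavelet denoising of a (binned) frame.

    Decomposes to ``params.levels``, estimates sigma once from the
    finest-scale diagonal detail subband, computes a per-subband threshold
    from that sigma and the subband coefficient count, shrinks every detail
    subband, keeps the approximation, and reconstructs.
    """
    params = params or WaveletParams()
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    levels = params.resolve_levels(image.shape[0])

    coeffs = pywt.wavedec2(image, params.family, level=levels, mode=params.mode)
    # coeffs[0] approximation; coeffs[-1] finest (cH, cV, cD)
    sigma = noise_sigma(coeffs[-1][2])
    shrunk = [coeffs[0]]
    for detail in coeffs[1:]:
        shrunk.append(
            tuple(soft_threshold(band, threshold_delta(sigma, band.size)) for band in detail)
        )
    out = pywt.waverec2(shrunk, params.family, mode=params.mode)
    return out[: image.shape[0], : image.shape[1]]


def preprocess_frame(
    frame: RawFrame,
    bg: BackgroundModel,
    bin_factor: int,
    params: WaveletParams | None = None,
) -> RawFrame:
    """Full stage: background subtraction, binning, wavelet denoising."""
    sub = subtract_background(frame, bg)
    binned = bin_pixels(sub.intensities, bin_factor)
    den = np.maximum(denoise_wavelet(binned, params), 0.0)
    return RawFrame(den, timestamp_s=frame.timestamp_s, position_mm=frame.position_mm)
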