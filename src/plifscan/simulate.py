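"""Forward simulator: plume fields and the camera frames they would produce.

Stands in for the instrument so every inverse stage is testable without
experimental data.  The scene is a continuous point source near the chamber
floor whose emitted puffs diffuse isotropically and rise with a buoyant
updraft; reflection at the six chamber walls is handled by the method of
images (one image per wall).  Superposing puffs over the emission history by
fixed-step time quadrature gives

    C(x, t) = sum_k q dt (2 pi s_k^2)^{-3/2} exp(-|x - c_k|^2 / (2 s_k^2))

with per-puff variance ``s_k^2 = 2 D (t - t_k)`` and center
``c_k = source + v (t - t_k) y_hat`` (plus its wall images).

Rendering inverts the processing chain forward: sample the field on the
oblique sheet through the coordinate shear, scale by the fan-beam
illumination ratio, optionally attenuate along laser and camera paths, then
add sensor background, seeded noise, and 16-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .attenuation import OpticalProperties
from .config import PlatformTrajectory, SystemConfig, frame_positions
from .illumination import correction_ratio
from .preprocess import RawFrame
from .reconstruct import FrameSequence, VoxelVolume, volume_grid

__all__ = [
    "PlumeScene",
    "CameraNoiseModel",
    "concentration_field",
    "render_frame",
    "render_background",
    "simulate_scan",
]


@dataclass(frozen=True)
class PlumeScene:
    """Ground-truth aerosol scene in the chamber.

    A point source at ``source_position_mm`` (nozzle in the lower part of the
    chamber) emits ``emission_rate`` concentration-units of tracer per second
    for ``source_duration_s``; puffs spread with ``diffusion_mm2_s`` and rise
    at ``rise_velocity_mm_s``.  ``uniform_concentration`` adds a spatially
    uniform component (useful for flat-field and attenuation round trips).
    """

    source_position_mm: tuple[float, float, float] = (250.0, 30.0, 250.0)
    emission_rate: float = 1.0
    diffusion_mm2_s: float = 150.0
    rise_velocity_mm_s: float = 10.0
    source_duration_s: float = 50.0
    uniform_concentration: float = 0.0
    chamber_dims_mm: tuple[float, float, float] = (500.0, 500.0, 1000.0)
    quad_dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.emission_rate < 0 or self.uniform_concentration < 0:
            raise ValueError("emission rate and uniform concentration must be >= 0")
        if self.diffusion_mm2_s <= 0:
            raise ValueError("diffusion coefficient must be > 0")
        if self.quad_dt_s <= 0:
            raise ValueError("quadrature step must be > 0")
        dims = self.chamber_dims_mm
        if any(not (0.0 <= s <= d) for s, d in zip(self.source_position_mm, dims)):
            raise ValueError("source must lie inside the chamber")


@dataclass(frozen=True)
class CameraNoiseModel:
    """Additive sensor model: constant offset, read noise, optional shot noise.

    Identical seeds (and frame keys) produce bit-identical frames.  Frames are
    quantized to integer counts in the 16-bit range whenever a noise model is
    present.
    """

    background_offset: float = 100.0
    read_noise_sigma: float = 2.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_offset < 0 or self.read_noise_sigma < 0:
            raise ValueError("offset and read noise sigma must be >= 0")


# -- plume field -----------------------------------------------------------


def _image_centers(center: np.ndarray, dims: tuple[float, float, float]) -> np.ndarray:
    """Original puff center plus its six single-wall mirror images, (7, 3)."""
    out = [center]
    for axis in range(3):
        for wall in (0.0, dims[axis]):
            img = center.copy()
            img[axis] = 2.0 * wall - center[axis]
            out.append(img)
    return np.asarray(out)


def _terms(scene: PlumeScene, t: float):
    """Quadrature terms (weights, centers (K,3), variances) at time t."""
    t_on = min(t, scene.source_duration_s)
    if scene.emission_rate <= 0 or t_on <= 0:
        return np.empty(0), np.empty((0, 3)), np.empty(0)
    dt = scene.quad_dt_s
    n_steps = max(int(np.ceil(t_on / dt)), 1)
    dt = t_on / n_steps  # exact cover of the emission interval
    t_emit = (np.arange(n_steps) + 0.5) * dt
    age = t - t_emit
    src = np.asarray(scene.source_position_mm, dtype=float)
    centers = []
    for a in age:
        c = src + np.array([0.0, scene.rise_velocity_mm_s * a, 0.0])
        centers.append(_image_centers(c, scene.chamber_dims_mm))
    centers = np.concatenate(centers)  # (n_steps*7, 3)
    variances = np.repeat(2.0 * scene.diffusion_mm2_s * age, 7)
    weights = np.full(len(variances), scene.emission_rate * dt)
    return weights, centers, variances


def concentration_field(scene: PlumeScene, t: float, query_points) -> np.ndarray:
    """Ground-truth concentration at chamber points (N, 3) at time t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    pts = np.atleast_2d(np.asarray(query_points, dtype=float))
    dims = scene.chamber_dims_mm
    if np.any(pts < -1e-9) or np.any(pts > np.asarray(dims) + 1e-9):
        raise ValueError("query points must lie inside the chamber")
    return _field_free(scene, t, pts)


def _field_free(scene: PlumeScene, t: float, pts: np.ndarray) -> np.ndarray:
    """Field evaluation without the chamber-bounds check (free-space form)."""
    w, centers, var = _terms(scene, t)
    out = np.full(len(pts), scene.uniform_concentration, dtype=float)
    if len(w):
        # chunk over terms to bound memory
        for lo in range(0, len(w), 512):
            sl = slice(lo, lo + 512)
            d2 = ((pts[None, :, :] - centers[sl, None, :]) ** 2).sum(axis=2)
            v = var[sl, None]
            out += (
                w[sl, None] * (2.0 * np.pi * v) ** -1.5 * np.exp(-d2 / (2.0 * v))
            ).sum(axis=0)
    return out


def field_on_grid(scene: PlumeScene, t: float, xs, ys, zs) -> np.ndarray:
    """Field on a regular grid, exploiting per-axis separability of each puff."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    w, centers, var = _terms(scene, t)
    out = np.full((len(xs), len(ys), len(zs)), scene.uniform_concentration)
    if len(w):
        s2 = var[:, None]
        gx = w[:, None] * (2.0 * np.pi * var[:, None]) ** -1.5 * np.exp(
            -((xs[None, :] - centers[:, 0:1]) ** 2) / (2.0 * s2))
        gy = np.exp(-((ys[None, :] - centers[:, 1:2]) ** 2) / (2.0 * s2))
        gz = np.exp(-((zs[None, :] - centers[:, 2:3]) ** 2) / (2.0 * s2))
        out += np.einsum("ka,kb,kc->abc", gx, gy, gz, optimize=True)
    return out


def _field_on_sheet(scene: PlumeScene, t: float, y: np.ndarray,
                    xz: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Field on an oblique sheet: rows share y, columns share (x, z)."""
    x, z = xz
    w, centers, var = _terms(scene, t)
    out = np.full((len(y), len(x)), scene.uniform_concentration)
    if len(w):
        s2 = var[:, None]
        gy = np.exp(-((y[None, :] - centers[:, 1:2]) ** 2) / (2.0 * s2))
        gxz = w[:, None] * (2.0 * np.pi * var[:, None]) ** -1.5 * np.exp(
            -(((x[None, :] - centers[:, 0:1]) ** 2)
              + ((z[None, :] - centers[:, 2:3]) ** 2)) / (2.0 * s2))
        out += gy.T @ gxz
    return out


# -- rendering -------------------------------------------------------------


def _inside_chamber(pts: np.ndarray, dims) -> np.ndarray:
    return np.all((pts >= 0.0) & (pts <= np.asarray(dims)), axis=-1)


def _path_attenuation(
    scene: PlumeScene,
    t: float,
    pixel_points: np.ndarray,
    p: float,
    config: SystemConfig,
    optics: OpticalProperties,
    n_nodes: int = 17,
) -> np.ndarray:
    """Detected ratio per pixel from laser-path and camera-path absorbances.

    Concentration outside the chamber contributes nothing (clean air); paths
    are integrated by the trapezoid rule over ``n_nodes`` samples.
    """
    c = config.plane_wall_cos
    apex = np.array([-config.r0_mm * c, 0.0, p - config.r0_mm * c])
    flat = pixel_points.reshape(-1, 3)

    def path_integral(starts, ends):
        length = np.linalg.norm(ends - starts, axis=1)
        s = np.linspace(0.0, 1.0, n_nodes)
        conc = np.empty((n_nodes, len(starts)))
        for i, si in enumerate(s):
            pts = starts + si * (ends - starts)
            vals = _field_free(scene, t, pts)
            vals[~_inside_chamber(pts, scene.chamber_dims_mm)] = 0.0
            conc[i] = vals
        return np.trapezoid(conc, dx=1.0 / (n_nodes - 1), axis=0) * length

    a_ex = optics.eps_ex * path_integral(np.broadcast_to(apex, flat.shape).copy(), flat)
    normal = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
    cam = flat + config.imaging_distance_mm * normal
    a_em = optics.eps_em * path_integral(flat, cam)
    ratio = 10.0 ** (-(a_ex + a_em) / 2.0)
    return ratio.reshape(pixel_points.shape[:-1])


def render_frame(
    scene: PlumeScene,
    t: float,
    p: float,
    config: SystemConfig,
    noise: CameraNoiseModel | None = None,
    attenuation: OpticalProperties | None = None,
    gain: float = 1000.0,
    resolution: str = "sensor",
    frame_key: int = 0,
) -> RawFrame:
    """Render the frame the camera would record at time t, sheet position p.

    With ``noise=None`` the ideal float frame (concentration x illumination
    x gain, no offset, no quantization) is returned so exact round trips are
    possible; a noise model adds its offset and noise and quantizes to
    integer counts in the 16-bit range.  ``resolution`` is ``"sensor"`` or
    ``"binned"`` (render directly on the binned lattice).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if not (0.0 <= p <= max(scene.chamber_dims_mm)):
        raise ValueError(f"sheet position {p} mm outside the chamber")
    side = config.sensor_pixels if resolution == "sensor" else config.binned_pixels
    if resolution not in ("sensor", "binned"):
        raise ValueError("resolution must be 'sensor' or 'binned'")
    px = config.imaging_plane_extent_mm / side
    cang = config.plane_wall_cos
    m = np.arange(side, dtype=float) * px  # along sheet (columns)
    n = np.arange(side, dtype=float) * px  # vertical (rows)
    x = m * cang
    z = p + m * cang

    conc = _field_on_sheet(scene, t, n, (x, z))
    illum = correction_ratio(m[None, :], n[:, None], config.r0_mm)
    signal = gain * conc * illum
    if attenuation is not None:
        pix = np.empty((side, side, 3))
        pix[..., 0] = x[None, :]
        pix[..., 1] = n[:, None]
        pix[..., 2] = z[None, :]
        signal = signal * _path_attenuation(scene, t, pix, p, config, attenuation)

    if noise is not None:
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, frame_key]))
        signal = signal + noise.background_offset
        if noise.shot_noise:
            signal = signal + rng.normal(0.0, np.sqrt(np.maximum(signal, 0.0)))
        if noise.read_noise_sigma > 0:
            signal = signal + rng.normal(0.0, noise.read_noise_sigma, signal.shape)
        signal = np.clip(np.rint(signal), 0, 65535)
    else:
        signal = np.maximum(signal, 0.0)
    return RawFrame(signal, timestamp_s=t, position_mm=p)


def render_background(
    config: SystemConfig,
    noise: CameraNoiseModel,
    n_frames: int = 10,
    resolution: str = "sensor",
) -> list[RawFrame]:
    """Laser-on frames before any aerosol enters: offset plus noise only."""
    empty = PlumeScene(emission_rate=0.0, uniform_concentration=0.0,
                       chamber_dims_mm=(500.0, 500.0, 1000.0))
    return [
        render_frame(empty, t=0.0, p=0.0, config=config, noise=noise,
                     resolution=resolution, frame_key=10_000 + k)
        for k in range(n_frames)
    ]


def simulate_scan(
    scene: PlumeScene,
    trajectory: PlatformTrajectory,
    duration_s: float,
    config: SystemConfig,
    noise: CameraNoiseModel | None = None,
    attenuation: OpticalProperties | None = None,
    gain: float = 1000.0,
    window_duration_s: float = 5.0,
    resolution: str = "sensor",
    gt_time_samples: int = 3,
    freeze_time: bool = False,
    t_start_s: float = 0.0,
) -> tuple[FrameSequence, list[VoxelVolume]]:
    """Render a full platform sweep and the matching ground-truth volumes.

    Frames are rendered at ``1/frame_rate`` intervals at the trajectory's
    fold-back positions.  For each full reconstruction window the ground
    truth is the plume field sampled on the reconstruction voxel grid,
    averaged over ``gt_time_samples`` times spanning the window.  With
    ``freeze_time`` the scene is evaluated at the scan end time for every
    frame (a static scene).  ``t_start_s`` starts the scan that long after
    the source switches on (mid-injection imaging).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n_frames = round(duration_s * config.frame_rate_hz)
    times = t_start_s + np.arange(n_frames) / config.frame_rate_hz
    positions = frame_positions(trajectory, n_frames, config.frame_rate_hz)
    frames = []
    for k, (t, p) in enumerate(zip(times, positions)):
        t_eval = t_start_s + duration_s if freeze_time else float(t)
        frames.append(
            render_frame(scene, t_eval, float(p), config, noise=noise,
                         attenuation=attenuation, gain=gain,
                         resolution=resolution, frame_key=k)
        )
    seq = FrameSequence(
        frames=np.stack([f.intensities for f in frames]),
        positions_mm=positions,
        timestamps_s=times,
    )

    # ground truth per full window, on the lattice the reconstruction will use
    frames_per_window = round(config.frame_rate_hz * window_duration_s)
    n_windows = n_frames // frames_per_window
    side_binned = config.binned_pixels
    gt_volumes = []
    for kw in range(n_windows):
        sl = slice(kw * frames_per_window, (kw + 1) * frames_per_window)
        xs, ys, zs = volume_grid(positions[sl], (side_binned, side_binned), config)
        t_lo, t_hi = float(times[sl][0]), float(times[sl][-1])
        sample_times = (
            [t_start_s + duration_s] if freeze_time
            else np.linspace(t_lo, t_hi, max(gt_time_samples, 1))
        )
        acc = np.zeros((len(xs), len(ys), len(zs)))
        for ts in sample_times:
            acc += field_on_grid(scene, float(ts), xs, ys, zs)
        acc /= len(sample_times)
        gt_volumes.append(
            VoxelVolume(
                values=acc,
                spacing_mm=(
                    float(xs[1] - xs[0]) if len(xs) > 1 else 1.0,
                    float(ys[1] - ys[0]) if len(ys) > 1 else 1.0,
                    float(zs[1] - zs[0]) if len(zs) > 1 else 1.0,
                ),
                origin_mm=(0.0, 0.0, float(zs[0])),
                window_s=(t_lo, t_hi),
            )
        )
    return seq, gt_volumes
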