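"""End-to-end processing: denoise -> illumination-correct -> reconstruct.

The stage order is fixed: background subtraction, binning and wavelet
denoising first, then fan-beam illumination correction, then windowed 3D
reconstruction.  It is deliberately not configurable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SystemConfig
from .illumination import apply_correction, build_map
from .io import RunManifest, frames_to_sequence, read_frame_stack, write_volume
from .preprocess import BackgroundModel, RawFrame, WaveletParams, preprocess_frame
from .reconstruct import FrameSequence, VoxelVolume, reconstruct_volume, window_frames

__all__ = ["process_frames", "run_pipeline"]

logger = logging.getLogger(__name__)


def process_frames(
    frames: list[RawFrame],
    background: BackgroundModel,
    config: SystemConfig,
    wavelet: WaveletParams | None = None,
) -> FrameSequence:
    """Preprocess and illumination-correct raw frames into a FrameSequence."""
    if not frames:
        raise ValueError("no input frames")
    bin_factor = frames[0].shape[0] // config.binned_pixels
    if bin_factor < 1 or frames[0].shape[0] % config.binned_pixels:
        raise ValueError(
            f"frame side {frames[0].shape[0]} incompatible with "
            f"{config.binned_pixels} binned pixels"
        )
    cmap = build_map(config)
    processed = []
    for f in frames:
        pre = preprocess_frame(f, background, bin_factor, wavelet)
        corrected = apply_correction(pre.intensities, cmap)
        processed.append(RawFrame(corrected, pre.timestamp_s, pre.position_mm))
    return frames_to_sequence(processed)


def _summarise(volumes: list[VoxelVolume]) -> pd.DataFrame:
    rows = []
    for k, v in enumerate(volumes):
        mask = v.measured_mask
        vals = np.where(mask, v.values, 0.0)
        cx, cy, cz = v.centroid_mm()
        rows.append(
            {
                "window": k,
                "t_start_s": v.window_s[0],
                "t_end_s": v.window_s[1],
                "total_intensity": float(vals.sum()),
                "centroid_x_mm": cx,
                "centroid_y_mm": cy,
                "centroid_z_mm": cz,
                "occupied_voxel_fraction": float(mask.mean()),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: SystemConfig,
    input_stack,
    input_sidecar,
    background_stack,
    output_dir,
    window_duration_s: float = 5.0,
    wavelet: WaveletParams | None = None,
    interpolate_z: bool = False,
) -> tuple[list[VoxelVolume], RunManifest]:
    """Run the full chain on stored stacks and write volumes + manifest."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if background_stack is None:
        raise ValueError(
            "a pre-injection background stack is required: the pipeline "
            "subtracts laser-on background noise before denoising"
        )
    try:
        raw = read_frame_stack(input_stack, input_sidecar)
    except Exception as exc:
        raise RuntimeError(f"stage 'read input': {exc}") from exc
    try:
        bg = BackgroundModel.from_frames(read_frame_stack(background_stack))
    except Exception as exc:
        raise RuntimeError(f"stage 'read background': {exc}") from exc
    try:
        seq = process_frames(raw, bg, config, wavelet)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess/correct': {exc}") from exc
    try:
        windows = window_frames(seq, window_duration_s, config.frame_rate_hz)
        volumes = [reconstruct_volume(w, config, interpolate_z) for w in windows]
    except Exception as exc:
        raise RuntimeError(f"stage 'reconstruct': {exc}") from exc

    for k, vol in enumerate(volumes):
        write_volume(output_dir / f"volume_{k:03d}", vol)
    _summarise(volumes).to_csv(output_dir / "summary.csv", index=False)
    wl = wavelet or WaveletParams()
    manifest = RunManifest.build(
        config,
        parameters={
            "window_duration_s": window_duration_s,
            "wavelet_family": wl.family,
            "wavelet_levels": wl.levels,
            "boundary_mode": wl.mode,
            "interpolate_z": interpolate_z,
            "stage_order": ["background_subtraction", "binning",
                            "wavelet_denoise", "illumination_correction",
                            "reconstruction"],
        },
        inputs={"input_stack": input_stack, "background_stack": background_stack,
                **({"input_sidecar": input_sidecar} if input_sidecar else {})},
    )
    manifest.write(output_dir / "manifest.json")
    return volumes, manifest
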