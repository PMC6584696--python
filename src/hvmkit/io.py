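"""Sequence I/O, device calibration, quality gating, and result tables.

Handheld vital microscopy (HVM) devices differ in sensor geometry and
optics, so physical units enter the pipeline through a :class:`DeviceProfile`
carrying the pixel pitch (um per pixel at the object plane) and frame rate.
Supported containers are multi-page TIFF stacks and directories of numbered
PNG/TIFF frames; stabilized output is written as lossless multi-page TIFF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread

if TYPE_CHECKING:  # pragma: no cover
    from .detection import VesselSegment
    from .metrics import FieldMetrics
    from .velocimetry import RBCPath

#: Rec. 601 luminance weights for color -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Massey quality scores below this are considered analyzable.
MASSEY_CUTOFF = 10.0


@dataclass(frozen=True)
class DeviceProfile:
    """Calibration constants of one HVM device / container combination."""

    name: str
    pixel_pitch: float            # um per pixel at the object plane
    native_width: int = 0         # px; 0 = unconstrained
    native_height: int = 0
    default_frame_rate: float = 25.0   # s^-1

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.default_frame_rate <= 0:
            raise ValueError("default_frame_rate must be > 0")


#: Profiles for common devices. Pitches are representative values; per-device
#: calibration against a micrometer target should override them in the config.
BUILTIN_PROFILES = {
    "generic_sdf": DeviceProfile("generic_sdf", pixel_pitch=1.3, native_width=720,
                                 native_height=576, default_frame_rate=25.0),
    "generic_idf": DeviceProfile("generic_idf", pixel_pitch=0.7, native_width=1280,
                                 native_height=1024, default_frame_rate=30.0),
}


class ImageSequence:
    """Ordered grayscale frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape (T, H, W); any real dtype, values on the recording's
        gray scale (0..255 for 8-bit input).
    frame_rate
        Frames per second.
    pixel_pitch
        Micrometers per pixel at the object plane.
    """

    def __init__(self, frames: np.ndarray, frame_rate: float, pixel_pitch: float):
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError("frames must have shape (T, H, W)")
        if frame_rate <= 0 or pixel_pitch <= 0:
            raise ValueError("frame_rate and pixel_pitch must be > 0")
        self.frames = frames
        self.frame_rate = float(frame_rate)
        self.pixel_pitch = float(pixel_pitch)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def fov_area(self) -> float:
        """Field-of-view area in mm^2: H * W * pitch^2 * 1e-6."""
        h, w = self.shape
        return h * w * self.pixel_pitch ** 2 * 1e-6

    def as_float(self) -> np.ndarray:
        return self.frames.astype(np.float64, copy=False)

    def copy_with(self, frames: np.ndarray) -> "ImageSequence":
        return ImageSequence(frames, self.frame_rate, self.pixel_pitch)


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return (frame[..., :3].astype(np.float64) @ _LUMA).round().astype(frame.dtype)
    raise ValueError(f"unsupported frame shape {frame.shape}")


def load_sequence(
    path: str | Path,
    profile: DeviceProfile,
    frame_rate: float | None = None,
) -> ImageSequence:
    """Read a multi-page TIFF or a directory of numbered frames.

    Color frames are converted to gray by luminance weighting. Pixel pitch
    and frame rate are taken from the device profile unless ``frame_rate``
    overrides the latter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no image frames found in {path}")
        raw = [np.asarray(imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        raw = list(stack)
    else:
        raise ValueError(f"unsupported container: {path.suffix!r} "
                         "(expected .tif/.tiff or a frame directory)")
    frames = [_to_gray(f) for f in raw]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame size: {sorted(shapes)}")
    if not frames:
        raise ValueError("empty sequence")
    return ImageSequence(
        np.stack(frames),
        frame_rate if frame_rate is not None else profile.default_frame_rate,
        profile.pixel_pitch,
    )


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as lossless multi-page TIFF (bit-identical round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")


def quality_gate(massey_score: float) -> bool:
    """Accept a sequence for analysis iff its Massey quality score is < 10.

    The score is supplied by the operator; automated quality scoring is out
    of scope. Returns True (accept) or False (reject).
    """
    if massey_score < 0:
        raise ValueError("Massey score must be non-negative")
    return massey_score < MASSEY_CUTOFF


def write_outputs(
    metrics: "FieldMetrics",
    vessels: Sequence["VesselSegment"],
    paths: Sequence["RBCPath"],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three result tables (per-field, per-vessel, per-path) as CSV.

    Every analyzed entity yields exactly one row; units follow the field
    conventions (mm mm^-2 for densities, um and um/s for geometry and
    velocity, categorical perfusion and vessel-type labels).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    field_df = pd.DataFrame([{
        "tvd_mm_per_mm2": metrics.tvd,
        "fcd_mm_per_mm2": metrics.fcd,
        "ppv": metrics.ppv,
        "rbcv_um_per_s": metrics.rbcv if metrics.rbcv is not None else np.nan,
        "fov_area_mm2": metrics.fov_area,
        "n_capillaries": metrics.n_capillaries,
        "n_venules": metrics.n_venules,
        "n_paths": metrics.n_paths,
    }])

    vessel_rows = [{
        "vessel_id": v.id,
        "vessel_type": v.vessel_type,
        "length_um": v.length,
        "mean_diameter_um": v.mean_diameter,
        "rbcv_um_per_s": v.rbcv if v.rbcv is not None else np.nan,
        "perfusion": v.perfusion if v.perfusion is not None else "",
        "v_max_um_per_s": v.v_max if v.v_max is not None else np.nan,
    } for v in vessels]
    vessel_df = pd.DataFrame(
        vessel_rows,
        columns=["vessel_id", "vessel_type", "length_um", "mean_diameter_um",
                 "rbcv_um_per_s", "perfusion", "v_max_um_per_s"],
    )

    path_rows = [{
        "path_id": i,
        "vessel_id": p.vessel_id,
        "velocity_um_per_s": p.velocity,
        "curvature_index": p.curvature_index,
        "path_type": p.path_type,
        "n_points": len(p.points),
    } for i, p in enumerate(paths)]
    path_df = pd.DataFrame(
        path_rows,
        columns=["path_id", "vessel_id", "velocity_um_per_s",
                 "curvature_index", "path_type", "n_points"],
    )

    out = {
        "field": out_dir / "field.csv",
        "vessels": out_dir / "vessels.csv",
        "paths": out_dir / "paths.csv",
    }
    field_df.to_csv(out["field"], index=False)
    vessel_df.to_csv(out["vessels"], index=False)
    path_df.to_csv(out["paths"], index=False)
    return out
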