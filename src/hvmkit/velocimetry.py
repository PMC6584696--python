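"""Space-time-diagram (kymograph) red-blood-cell velocimetry.

For each capillary, the gray values along the straightened centerline are
read out from every frame of the enhanced stabilized sequence and appended
as columns: the space-time diagram. A moving cell appears as a sloped dark
band whose slope encodes its velocity; stationary cells produce horizontal
banding (the "barcode sign"), and global frame-brightness flicker would
produce vertical stripes, which per-frame histogram equalization removes
beforehand.

The same principal-curvature line detector used for vessel recognition is
applied to each diagram; the resulting centerlines are the RBC paths. The
per-path velocity is the mean absolute space derivative by time, scaled by
pixel pitch and frame rate. Paths are discarded as artifacts if too short,
too curved (low curvature index), or faster than the per-vessel detection
limit v_max = l*f/3. The vessel RBCv is the mean of the surviving paths,
and the vessel is classified perfused when more than 95% of its paths show
normal flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .detection import (VesselSegment, chain_fragments, equalize_global,
                        link_line_points, steger_detect)
from .io import ImageSequence


@dataclass
class SpaceTimeDiagram:
    """Intensity map: rows = centerline arclength (px), columns = frames."""

    matrix: np.ndarray          # (S, T)
    pixel_pitch: float          # um/px along the space axis
    frame_rate: float           # s^-1 along the time axis
    vessel_id: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or min(self.matrix.shape) < 2:
            raise ValueError("diagram must be at least 2x2")
        if self.pixel_pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("axis scales must be positive")


@dataclass
class RBCPath:
    """One tracked red blood cell: ordered (space px, time frames) samples."""

    points: np.ndarray          # (N, 2) columns: space, time; oriented forward in time
    vessel_id: int = -1
    velocity: float = 0.0       # um/s, magnitude
    curvature_index: float = 1.0
    path_type: str = "unclassified"   # no_low_flow | normal_flow | artifact

    @property
    def arclength_px(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# per-frame enhancement
# ---------------------------------------------------------------------------

def enhance_frames(seq: ImageSequence, smooth_sigma: float = 1.0) -> ImageSequence:
    """Histogram-equalize then Gaussian-smooth each frame independently.

    Equalizing every frame against its own histogram cancels inter-frame
    brightness flicker, which would otherwise imprint vertical stripes on
    the diagrams; smoothing suppresses sensor noise.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames")
    out = np.empty(seq.frames.shape, dtype=np.float64)
    for i, frame in enumerate(seq.as_float()):
        eq = equalize_global(frame)
        out[i] = ndimage.gaussian_filter(eq, smooth_sigma) if smooth_sigma > 0 else eq
    return seq.copy_with(out)


# ---------------------------------------------------------------------------
# diagram construction
# ---------------------------------------------------------------------------

def resample_centerline(points_px: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline at equidistant arclength positions (px)."""
    deltas = np.linalg.norm(np.diff(points_px, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(deltas)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate centerline")
    n = max(int(round(total / spacing)) + 1, 2)
    si = np.linspace(0, total, n)
    return np.column_stack([np.interp(si, s, points_px[:, 0]),
                            np.interp(si, s, points_px[:, 1])])


def build_space_time_diagram(seq: ImageSequence, vessel: VesselSegment,
                             spacing: float = 1.0) -> SpaceTimeDiagram:
    """Sample the centerline in every frame and append columns over time.

    Intensities are bilinearly interpolated at ~1 px arclength spacing;
    centerline samples outside the (possibly cropped) frame are trimmed to
    the largest interior run. The finished diagram is histogram-equalized.
    """
    pts = vessel.points_px
    if len(pts) < 2:
        raise ValueError("centerline needs at least 2 points")
    samples = resample_centerline(pts, spacing)
    h, w = seq.shape
    inside = ((samples[:, 0] >= 0) & (samples[:, 0] <= h - 1)
              & (samples[:, 1] >= 0) & (samples[:, 1] <= w - 1))
    if not inside.all():
        runs = np.split(np.arange(len(samples)), np.nonzero(np.diff(inside))[0] + 1)
        runs = [r for r in runs if inside[r[0]]]
        if not runs:
            raise ValueError("centerline lies outside the field of view")
        samples = samples[max(runs, key=len)]
    if len(samples) < 2:
        raise ValueError("centerline too short inside the field of view")

    coords = samples.T    # (2, S)
    cols = [ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
            for frame in seq.as_float()]
    matrix = equalize_global(np.stack(cols, axis=1))
    return SpaceTimeDiagram(matrix=matrix, pixel_pitch=seq.pixel_pitch,
                            frame_rate=seq.frame_rate, vessel_id=vessel.id)


# ---------------------------------------------------------------------------
# path detection and per-path measures
# ---------------------------------------------------------------------------

def detect_rbc_paths(std: SpaceTimeDiagram,
                     config: AnalysisConfig | None = None) -> list[RBCPath]:
    """Steger detection + linking inside the diagram; one path per centerline.

    Detected polylines live in (space, time) coordinates; each is reordered
    by time so the velocity derivative is well defined.
    """
    config = config or AnalysisConfig()
    points = steger_detect(std.matrix, config.std_sigma, config.std_high,
                           config.std_low)
    lines = link_line_points(points, config.std_link_h, config.std_link_l,
                             min_length=2.0)
    polylines = [np.array([[p.row, p.col] for p in line]) for line in lines]
    polylines = _merge_fragments(polylines, max_dist=config.std_merge_dist,
                                 max_angle=config.std_merge_angle)
    paths = []
    for pts in polylines:
        if pts[-1, 1] < pts[0, 1]:
            pts = pts[::-1]    # orient forward in time; geometry order preserved
        paths.append(RBCPath(points=pts, vessel_id=std.vessel_id))
    return paths


def _merge_fragments(polylines: list[np.ndarray], max_dist: float,
                     max_angle: float) -> list[np.ndarray]:
    """Join polyline fragments whose ends meet collinearly.

    Greedy seeding fragments one RBC streak into pieces wherever the ridge
    response dips (cell-cluster hand-offs between frames); see
    :func:`hvmkit.detection.chain_fragments` for the matching rules.
    """
    polylines = [p for p in polylines if len(p) >= 2]
    chains = chain_fragments(polylines, max_dist, max_angle)
    return [np.vstack([polylines[i][::-1] if rev else polylines[i]
                       for i, rev in chain])
            for chain in chains]


def path_velocity(path: RBCPath, pixel_pitch: float, frame_rate: float) -> float:
    """Magnitude of the time-averaged d(space)/d(time) over the path, in um/s.

    The time average of the first derivative telescopes to the chord slope
    (s_end - s_start)/(t_end - t_start); it is evaluated over the central
    80% of the time-sorted samples because the ridge detector loses support
    at track ends and curls them. The mean is taken signed and the
    magnitude applied last: rectifying each step would bias wiggly but
    straight tracks upward.
    """
    pts = path.points
    if len(pts) < 2:
        raise ValueError("path needs at least 2 points")
    order = np.argsort(pts[:, 1], kind="stable")
    t = pts[order, 1]
    s = pts[order, 0]
    n = len(t)
    lo = int(0.1 * n)
    hi = max(n - lo, lo + 2)
    tt, ss = t[lo:hi], s[lo:hi]
    if tt[-1] - tt[0] <= 1e-9:        # try the full span before giving up
        tt, ss = t, s
    if tt[-1] - tt[0] <= 1e-9:
        raise ValueError("path spans zero frames")
    slope = (ss[-1] - ss[0]) / (tt[-1] - tt[0])
    return float(abs(slope)) * pixel_pitch * frame_rate


def curvature_index(path: RBCPath) -> float:
    """Straight-line endpoint distance over actual path length, in (0, 1]."""
    pts = path.points
    if len(pts) < 2:
        raise ValueError("degenerate single-point path")
    total = path.arclength_px
    if total <= 0:
        raise ValueError("zero-length path")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    return min(chord / total, 1.0)


def compute_vmax(vessel_length_um: float, frame_rate: float) -> float:
    """Maximum detectable RBC velocity: v_max = l * f / 3 (um/s).

    A cell must remain inside the vessel for ~3 frames to form a traceable
    band, so longer vessels and faster frame rates raise the ceiling.
    """
    if vessel_length_um < 0 or frame_rate <= 0:
        raise ValueError("need l >= 0 and f > 0")
    return vessel_length_um * frame_rate / 3.0


def classify_paths(paths: list[RBCPath], pixel_pitch: float, frame_rate: float,
                   v_max: float, config: AnalysisConfig | None = None) -> list[RBCPath]:
    """Apply the three artifact rules, then the low/normal flow split.

    A path is an artifact if it is shorter than ``min_path_length`` px, if
    it spans fewer frames than a traceable cell must (min_path_frames,
    mirroring the v_max = l f / 3 rationale), if its curvature index falls
    below the cutoff, or if its velocity exceeds v_max. Survivors with
    velocity below ``low_flow_cutoff`` are no_low_flow, the rest
    normal_flow.
    """
    config = config or AnalysisConfig()
    for p in paths:
        try:
            p.velocity = path_velocity(p, pixel_pitch, frame_rate)
            p.curvature_index = curvature_index(p)
        except ValueError:
            p.path_type = "artifact"
            continue
        t_span = float(p.points[-1, 1] - p.points[0, 1])
        if (p.arclength_px < config.min_path_length
                or t_span < config.min_path_frames
                or p.curvature_index < config.curvature_index_cutoff
                or p.velocity > v_max):
            p.path_type = "artifact"
        elif p.velocity < config.low_flow_cutoff:
            p.path_type = "no_low_flow"
        else:
            p.path_type = "normal_flow"
    return paths


def vessel_rbcv(paths: list[RBCPath]) -> float | None:
    """Mean velocity of non-artifact paths; None if none remain."""
    vels = [p.velocity for p in paths if p.path_type in ("no_low_flow", "normal_flow")]
    if not vels:
        return None
    return float(np.mean(vels))


def classify_perfusion(paths: list[RBCPath],
                       config: AnalysisConfig | None = None) -> str:
    """Perfused / non-perfused from the per-vessel path-velocity distribution.

    Barcode rule first: if more than the perfusion fraction (default 95%)
    of non-artifact path velocities lie below the low-flow cutoff, the
    vessel is non-perfused regardless of a fast minority. Otherwise the
    vessel is perfused iff the normal-flow fraction exceeds the threshold.
    In "normal_fit" mode the fraction is evaluated as the mass of a normal
    distribution fitted to the per-path velocities beyond 2 sigma.
    """
    config = config or AnalysisConfig()
    kept = [p for p in paths if p.path_type in ("no_low_flow", "normal_flow")]
    if not kept:
        return "non_perfused"
    vels = np.array([p.velocity for p in kept])
    thr = config.perfusion_fraction

    if config.perfusion_mode == "normal_fit":
        mu, sd = vels.mean(), vels.std()
        if sd < 1e-9:
            slow_frac = float(np.mean(vels < config.low_flow_cutoff))
            return "non_perfused" if slow_frac > thr else (
                "perfused" if 1 - slow_frac > thr else "non_perfused")
        from scipy.stats import norm
        slow_mass = norm.cdf(config.low_flow_cutoff, mu, sd)
        if slow_mass > thr:
            return "non_perfused"
        return "perfused" if 1 - slow_mass > thr else "non_perfused"

    slow_frac = float(np.mean(vels < config.low_flow_cutoff))
    if slow_frac > thr:
        return "non_perfused"
    normal_frac = float(np.mean([p.path_type == "normal_flow" for p in kept]))
    return "perfused" if normal_frac > thr else "non_perfused"


def analyze_vessel(seq: ImageSequence, vessel: VesselSegment,
                   config: AnalysisConfig | None = None) -> list[RBCPath]:
    """Full velocimetry for one capillary on an already-enhanced sequence.

    Builds the diagram, detects and classifies paths, and fills the
    vessel's rbcv, v_max and perfusion fields in place.
    """
    config = config or AnalysisConfig()
    vessel.v_max = compute_vmax(vessel.length, seq.frame_rate)
    try:
        std = build_space_time_diagram(seq, vessel)
    except ValueError:
        vessel.perfusion = "non_perfused"
        return []
    paths = detect_rbc_paths(std, config)
    paths = classify_paths(paths, seq.pixel_pitch, seq.frame_rate,
                           vessel.v_max, config)
    vessel.rbcv = vessel_rbcv(paths)
    vessel.perfusion = classify_perfusion(paths, config)
    return paths
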