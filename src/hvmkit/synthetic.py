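"""Synthetic handheld-vital-microscopy scene generator with exact ground truth.

Real HVM recordings show bright tissue with dark, moving red blood cells
confined to curvilinear capillaries, separated by plasma gaps, and degraded
by global brightness flicker, translational/rotational camera jitter and
sensor noise. The generator renders exactly that: anisotropic Gaussian
cells advected along spline centerlines at prescribed velocities,
composited on a textured background, with every degradation injected with
known per-frame parameters. Each scene returns a :class:`GroundTruth`
carrying true centerlines, lengths, diameters, velocities, perfusion
labels, per-frame camera motion, and the analytic field metrics, so every
pipeline stage can be validated without real recordings.

All randomness flows from the single scene seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .io import ImageSequence

#: Rendered cell length along the flow direction, um (red-blood-cell scale).
CELL_LENGTH_UM = 7.0
_FWHM = 2.355  # FWHM of a unit-sigma Gaussian


@dataclass
class VesselSpec:
    """One synthetic tube: geometry plus flow program."""

    control_points: list[tuple[float, float]]   # (row, col) px
    diameter_um: float
    velocity_um_s: float = 0.0                  # 0 renders static cells (barcode)
    cell_spacing_um: float = 15.0               # plasma-gap period
    cell_contrast: float = 80.0                 # gray-level depth of one cell
    intermittency: np.ndarray | None = None     # bool per frame; None = always on


@dataclass
class SceneSpec:
    width: int = 256
    height: int = 256
    n_frames: int = 80
    frame_rate: float = 25.0         # s^-1
    pixel_pitch: float = 1.3         # um/px
    background_level: float = 180.0  # gray
    background_texture: float = 6.0  # gray, sd of static low-frequency texture
    vessels: list[VesselSpec] = field(default_factory=list)
    noise_sd: float = 0.0            # gray, additive sensor noise
    flicker_amplitude: float = 0.0   # gray, global per-frame offset
    jitter_amplitude: float = 0.0    # px, per-frame random translation
    exposure_fraction: float = 1.0   # sensor exposure as a fraction of the frame period
    jitter: np.ndarray | None = None     # (T, 2) explicit (ty, tx), overrides amplitude
    rotations: np.ndarray | None = None  # (T,) radians about the frame center
    seed: int = 0


@dataclass
class VesselTruth:
    centerline_px: np.ndarray       # dense subpixel (row, col) samples
    length_um: float
    diameter_um: float
    velocity_um_s: float
    perfused: bool


@dataclass
class GroundTruth:
    vessels: list[VesselTruth]
    jitter: np.ndarray              # (T, 2) injected (ty, tx) px
    rotations: np.ndarray           # (T,) injected radians
    flicker: np.ndarray             # (T,) injected gray offsets
    fov_area: float                 # mm^2
    tvd: float                      # analytic, mm mm^-2
    fcd: float
    ppv: float
    rbcv: float | None              # analytic length-weighted mean, um/s


def _spline_centerline(control_points: list[tuple[float, float]],
                       step_px: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Dense (row, col) samples and tangent angles of a chord-length spline."""
    pts = np.asarray(control_points, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("need at least 2 control points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if len(pts) == 2:
        n = max(int(chord[-1] / step_px), 2)
        u = np.linspace(0, chord[-1], n)
        samples = np.column_stack([np.interp(u, chord, pts[:, 0]),
                                   np.interp(u, chord, pts[:, 1])])
    else:
        cs = CubicSpline(chord, pts, axis=0)
        u = np.arange(0, chord[-1], step_px)
        samples = cs(u)
    tangents = np.gradient(samples, axis=0)
    angles = np.arctan2(tangents[:, 1], tangents[:, 0])
    return samples, angles


def _arclength(samples: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _add_blob(img: np.ndarray, cy: float, cx: float, angle: float,
              sigma_along: float, sigma_across: float, amplitude: float) -> None:
    """Subtract one anisotropic Gaussian cell footprint in place."""
    h, w = img.shape
    r = 3.0 * max(sigma_along, sigma_across)
    r0, r1 = int(max(cy - r, 0)), int(min(cy + r + 1, h))
    c0, c1 = int(max(cx - r, 0)), int(min(cx + r + 1, w))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dy + sa * dx          # along the flow direction
    v = -sa * dy + ca * dx
    img[r0:r1, c0:c1] -= amplitude * np.exp(
        -u ** 2 / (2 * sigma_along ** 2) - v ** 2 / (2 * sigma_across ** 2))


def render_scene(spec: SceneSpec,
                 low_flow_cutoff: float = 25.0) -> tuple[ImageSequence, GroundTruth]:
    """Render a scene and its exact ground truth.

    Cells advance along each tube by velocity/(pitch*frame_rate) px per
    frame (wrapping at the tube ends so density stays constant), camera
    motion is applied to all scene content, flicker as a global offset, and
    Gaussian noise last. Output is deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, n_frames = spec.height, spec.width, spec.n_frames
    px_per_frame_denom = spec.pixel_pitch * spec.frame_rate

    # camera motion
    if spec.jitter is not None:
        jitter = np.asarray(spec.jitter, dtype=np.float64)
    elif spec.jitter_amplitude > 0:
        jitter = rng.uniform(-spec.jitter_amplitude, spec.jitter_amplitude,
                             size=(n_frames, 2))
        jitter[0] = 0.0
    else:
        jitter = np.zeros((n_frames, 2))
    rotations = (np.asarray(spec.rotations, dtype=np.float64)
                 if spec.rotations is not None else np.zeros(n_frames))
    if spec.flicker_amplitude > 0:
        flicker = spec.flicker_amplitude * np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)
    else:
        flicker = np.zeros(n_frames)

    # static background texture, rendered oversized and warped with the camera
    pad = int(np.ceil(np.abs(jitter).max() + 0.1 * max(h, w) * np.abs(rotations).max())) + 4
    texture = np.zeros((h + 2 * pad, w + 2 * pad))
    if spec.background_texture > 0:
        # two-scale tissue texture: broad absorbance blotches plus a weak
        # finer granularity that gives stabilization corners to lock onto
        coarse = ndimage.gaussian_filter(rng.normal(0, 1, size=texture.shape), 6.0)
        fine = ndimage.gaussian_filter(rng.normal(0, 1, size=texture.shape), 3.0)
        texture = 0.9 * coarse / max(coarse.std(), 1e-12) \
            + 0.3 * fine / max(fine.std(), 1e-12)
        texture *= spec.background_texture / max(texture.std(), 1e-12)

    # vessel geometry and per-vessel cell programs
    centerlines, angles_all, truths, programs = [], [], [], []
    for vs in spec.vessels:
        samples, angles = _spline_centerline(vs.control_points)
        s = _arclength(samples)
        total_px = s[-1]
        diam_px = vs.diameter_um / spec.pixel_pitch
        if diam_px < 2:
            raise ValueError("vessel diameter below 2 px at this pitch")
        if (samples[:, 0].min() < 0 or samples[:, 0].max() > h - 1
                or samples[:, 1].min() < 0 or samples[:, 1].max() > w - 1):
            raise ValueError("vessel centerline outside the frame")
        spacing_px = vs.cell_spacing_um / spec.pixel_pitch
        cell_len_px = CELL_LENGTH_UM / spec.pixel_pitch
        if spacing_px < cell_len_px:
            raise ValueError("cell spacing smaller than the cell size")
        step_px_nominal = vs.velocity_um_s / px_per_frame_denom
        max_disp = step_px_nominal * n_frames
        # clustered cell trains: runs of nearly touching cells separated by
        # long plasma gaps, as in real capillary flow; the low-frequency
        # envelope this creates is what makes kymograph streaks traceable.
        # The train is long enough that fresh cells keep entering the tube
        # (no wrap-around, which would make fast scenes time-periodic).
        train_len = total_px + max_disp + 2 * spacing_px
        n_cells = max(int(train_len / spacing_px), 1)
        tight = rng.uniform(1.0, 1.5, size=n_cells) * cell_len_px
        wide = rng.uniform(1.5, 4.0, size=n_cells) * spacing_px
        gaps = np.where(rng.random(n_cells) < 0.35, wide, tight)
        gaps *= n_cells * spacing_px / gaps.sum()   # keep the mean spacing
        phases = total_px + spacing_px - np.cumsum(gaps)   # descend below 0
        contrasts = vs.cell_contrast * rng.uniform(0.7, 1.3, size=n_cells)
        step_px = vs.velocity_um_s / px_per_frame_denom
        on = (np.ones(n_frames, dtype=bool) if vs.intermittency is None
              else np.asarray(vs.intermittency, dtype=bool))
        disp = np.concatenate([[0.0], np.cumsum(step_px * on[:-1])])
        on_frac = float(on.mean())
        effective_v = vs.velocity_um_s  # speed while moving; what paths measure
        perfused = effective_v >= low_flow_cutoff and on_frac > 0.95
        truths.append(VesselTruth(
            centerline_px=samples,
            length_um=total_px * spec.pixel_pitch,
            diameter_um=vs.diameter_um,
            velocity_um_s=effective_v if on_frac > 0 else 0.0,
            perfused=perfused,
        ))
        centerlines.append((samples, s))
        angles_all.append(angles)
        programs.append((phases, disp, diam_px / _FWHM, cell_len_px / _FWHM,
                         contrasts, total_px, step_px, on))

    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    grid = np.mgrid[0:h, 0:w].astype(np.float64)
    for t in range(n_frames):
        theta, (jy, jx) = rotations[t], jitter[t]
        ca, sa = math.cos(theta), math.sin(theta)
        img = np.full((h, w), spec.background_level, dtype=np.float64)
        if spec.background_texture > 0:
            # inverse-map pixel coords through the camera transform
            dy, dx = grid[0] - cy0, grid[1] - cx0
            src_r = ca * dy + sa * dx + cy0 - jy + pad
            src_c = -sa * dy + ca * dx + cx0 - jx + pad
            img += ndimage.map_coordinates(texture, [src_r, src_c], order=3,
                                           mode="nearest")
        for (samples, s), angles, prog in zip(centerlines, angles_all, programs):
            phases, disp, sig_across, sig_along, contrasts, total_px, step_px, on = prog
            # exposure-time motion blur: integrate each cell over its motion
            # during the frame by superposing sub-exposure footprints
            travel = (step_px * spec.exposure_fraction) if on[t] else 0.0
            n_sub = min(int(np.ceil(travel / sig_along)) + 1, 96)
            sub = (np.arange(n_sub) + 0.5) / n_sub * travel
            ang_unwrapped = np.unwrap(angles)
            for phase, contrast in zip(phases, contrasts):
                pos = phase + disp[t] + sub
                pos = pos[(pos >= 0) & (pos <= total_px)]   # inside the tube
                if pos.size == 0:
                    continue
                rows = np.interp(pos, s, samples[:, 0])
                cols = np.interp(pos, s, samples[:, 1])
                angs = np.interp(pos, s, ang_unwrapped)
                for r0, c0, a0 in zip(rows, cols, angs):
                    dy0, dx0 = r0 - cy0, c0 - cx0
                    rr = ca * dy0 - sa * dx0 + cy0 + jy
                    cc = sa * dy0 + ca * dx0 + cx0 + jx
                    _add_blob(img, rr, cc, a0 + theta, sig_along, sig_across,
                              contrast / n_sub)
        img += flicker[t]
        if spec.noise_sd > 0:
            img += rng.normal(0, spec.noise_sd, size=img.shape)
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    fov_area = h * w * spec.pixel_pitch ** 2 * 1e-6
    cap = [v for v in truths if v.diameter_um <= 20.0]
    tvd = sum(v.length_um for v in cap) / 1000.0 / fov_area
    fcd = sum(v.length_um for v in cap if v.perfused) / 1000.0 / fov_area
    ppv = fcd / tvd if tvd > 0 else 0.0
    moving = [v for v in cap if v.velocity_um_s > 0]
    rbcv = (float(np.average([v.velocity_um_s for v in moving],
                             weights=[v.length_um for v in moving]))
            if moving else None)
    gt = GroundTruth(vessels=truths, jitter=jitter, rotations=rotations,
                     flicker=flicker, fov_area=fov_area,
                     tvd=tvd, fcd=fcd, ppv=ppv, rbcv=rbcv)
    return ImageSequence(frames, spec.frame_rate, spec.pixel_pitch), gt


# ---------------------------------------------------------------------------
# benchmark scenes
# ---------------------------------------------------------------------------

def density_benchmark_scene(seed: int = 0, noisy: bool = False,
                            size: int = 512, n_frames: int = 100) -> SceneSpec:
    """Multi-vessel density benchmark: eight capillaries and one venule.

    The noisy variant adds sensor noise, brightness flicker and camera
    jitter at levels typical of handheld recordings.
    """
    geometry = [(30, 40, 490, 90), (20, 140, 500, 170), (60, 250, 480, 230),
                (30, 330, 500, 380), (120, 20, 150, 500), (260, 40, 230, 500),
                (380, 30, 410, 490), (470, 120, 440, 480)]
    scale = size / 512.0
    vessels = [
        VesselSpec([(r0 * scale, c0 * scale), (r1 * scale, c1 * scale)],
                   diameter_um=d, velocity_um_s=v, cell_spacing_um=15.0)
        for (r0, c0, r1, c1), d, v in zip(
            geometry,
            [8.0, 10.0, 12.0, 7.0, 9.0, 11.0, 8.0, 10.0],
            [250.0, 350.0, 200.0, 400.0, 300.0, 280.0, 320.0, 220.0])
    ]
    vessels.append(VesselSpec([(500 * scale, 30 * scale), (480 * scale, 490 * scale)],
                              diameter_um=50.0, velocity_um_s=500.0,
                              cell_spacing_um=18.0))
    kw = (dict(noise_sd=4.0, flicker_amplitude=10.0, jitter_amplitude=1.5)
          if noisy else {})
    return SceneSpec(width=size, height=size, n_frames=n_frames,
                     vessels=vessels, seed=seed, **kw)


def velocity_sweep_scene(vmax_fraction: float, seed: int = 0,
                         n_tubes: int = 8) -> tuple[SceneSpec, float]:
    """Parallel short capillaries all flowing at a fraction of their v_max.

    Tubes are 80 px (104 um at 1.3 um/px) long, the length of a typical
    capillary, with hemodiluted cell trains (40 um mean spacing) and clean
    optics so the velocity estimate - not vessel detectability - is what
    the scene probes. Returns the scene and the injected velocity (um/s).
    """
    length_px = 80.0
    pitch, fps = 1.3, 25.0
    v_max = length_px * pitch * fps / 3.0
    v = vmax_fraction * v_max
    size = 384
    cols = np.arange(40.0, size - 30.0, 43.0)[:n_tubes]
    tubes = [VesselSpec([(size / 2 - length_px / 2, c),
                         (size / 2 + length_px / 2, c)],
                        diameter_um=10.0, velocity_um_s=v,
                        cell_spacing_um=40.0, cell_contrast=100.0)
             for c in cols]
    return SceneSpec(width=size, height=size, n_frames=120, frame_rate=fps,
                     pixel_pitch=pitch, vessels=tubes, seed=seed,
                     background_texture=3.0), v


# ---------------------------------------------------------------------------
# canonical test suite
# ---------------------------------------------------------------------------

def _straight(row0: float, col0: float, row1: float, col1: float):
    return [(row0, col0), (row1, col1)]


def _gentle_curve(size: int, margin: float = 30.0, bow: float = 12.0):
    mid = size / 2
    return [(margin, mid - bow), (mid, mid + bow), (size - margin, mid - bow)]


def default_suite(seed: int = 0) -> list[tuple[str, SceneSpec, dict]]:
    """Canonical scenes: the four flow archetypes plus density and stress.

    Returns (name, spec, expectations) triples; expectations hold the
    construction-time labels a correct pipeline should reproduce.
    """
    size = 256
    suite: list[tuple[str, SceneSpec, dict]] = []

    def tube(v, diameter=10.0, intermittency=None, spacing=20.0):
        return VesselSpec(control_points=_gentle_curve(size),
                          diameter_um=diameter, velocity_um_s=v,
                          cell_spacing_um=spacing, intermittency=intermittency)

    # tube arclength ~ 200 px -> l ~ 260 um, v_max ~ 2170 um/s at 25 fps
    suite.append(("normal_flow", SceneSpec(
        width=size, height=size, vessels=[tube(300.0)], seed=seed),
        {"perfusion": "perfused", "velocity": 300.0}))

    suite.append(("hyperdynamic", SceneSpec(
        width=size, height=size, vessels=[tube(1700.0)], seed=seed + 1),
        {"perfusion": "perfused", "velocity": 1700.0}))

    # MFI-1 archetype: flow absent well over half the time (10 on / 30 off)
    pattern = (np.arange(80) % 40) < 10
    suite.append(("intermittent", SceneSpec(
        width=size, height=size, vessels=[tube(300.0, intermittency=pattern)],
        seed=seed + 2),
        {"perfusion": "non_perfused", "velocity": 300.0}))

    suite.append(("no_flow", SceneSpec(
        width=size, height=size, vessels=[tube(0.0)], seed=seed + 3),
        {"perfusion": "non_perfused", "velocity": 0.0}))

    density_vessels = [
        VesselSpec(_straight(30, 20, 50, 236), diameter_um=8.0, velocity_um_s=250.0),
        VesselSpec(_straight(20, 60, 236, 90), diameter_um=10.0, velocity_um_s=350.0),
        VesselSpec(_straight(110, 20, 130, 236), diameter_um=12.0, velocity_um_s=200.0),
        VesselSpec(_straight(20, 170, 236, 200), diameter_um=7.0, velocity_um_s=400.0),
        VesselSpec(_straight(225, 20, 205, 236), diameter_um=50.0, velocity_um_s=500.0,
                   cell_spacing_um=18.0),
    ]
    suite.append(("density", SceneSpec(
        width=size, height=size, vessels=density_vessels, seed=seed + 4),
        {"n_capillaries": 4, "n_venules": 1}))

    suite.append(("stress", SceneSpec(
        width=size, height=size, vessels=density_vessels, seed=seed + 5,
        noise_sd=4.0, flicker_amplitude=10.0, jitter_amplitude=1.5),
        {"n_capillaries": 4, "n_venules": 1}))

    return suite
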