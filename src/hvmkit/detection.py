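"""Vessel recognition on the temporal mean image.

Vessels in handheld vital microscopy are visualized by the hemoglobin of
moving red blood cells, so single frames show fragmented dark blobs with
plasma gaps. Averaging the stabilized sequence over time fills the gaps and
yields continuous dark curvilinear bands. These are extracted by
principal-curvature line detection (Steger's method): the image is convolved
with first- and second-derivative Gaussian kernels, the Hessian eigenvector
of the largest-magnitude eigenvalue gives the line normal, and a subpixel
line point is accepted where the first directional derivative vanishes
inside the pixel and the second-derivative response passes hysteresis
thresholds. Line points are chained by an orientation-aware linking step and
per-point widths come from edge localization along the normal.

Two passes run at different scales - a capillary pass at full resolution and
a venule pass on a decimated image - and are superimposed with overlap
elimination. Mean diameter <= 20 um classifies a segment as capillary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .io import ImageSequence



# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LinePoint:
    """One subpixel centerline point with normal direction and local width (px)."""

    row: float
    col: float
    normal_angle: float   # radians in [0, pi)
    width: float          # px, full line width
    response: float = 0.0


@dataclass
class VesselSegment:
    """A detected vessel: ordered centerline with physical geometry.

    Lengths and diameters are in micrometers (converted via the pixel
    pitch); velocity and perfusion fields are filled by the velocimetry
    stage and remain None for vessels without usable space-time diagrams.
    """

    id: int
    centerline: list[LinePoint]
    pixel_pitch: float
    vessel_type: str = "capillary"     # "capillary" | "venule"
    rbcv: float | None = None          # um/s
    perfusion: str | None = None       # "perfused" | "non_perfused"
    v_max: float | None = None         # um/s

    @property
    def points_px(self) -> np.ndarray:
        return np.array([[p.row, p.col] for p in self.centerline])

    @property
    def length(self) -> float:
        """Centerline arclength in um (cumulative Euclidean steps x pitch)."""
        pts = self.points_px
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) * self.pixel_pitch

    @property
    def mean_diameter(self) -> float:
        """Mean of per-point widths in um."""
        if not self.centerline:
            return 0.0
        return float(np.mean([p.width for p in self.centerline])) * self.pixel_pitch


# ---------------------------------------------------------------------------
# mean image and CLAHE
# ---------------------------------------------------------------------------

def compute_mean_image(seq: ImageSequence) -> np.ndarray:
    """Per-pixel arithmetic mean over time (plasma-gap filling)."""
    if seq.n_frames < 1:
        raise ValueError("empty sequence")
    return seq.as_float().mean(axis=0)


def equalize_global(image: np.ndarray, n_bins: int = 256, g_max: float = 255.0) -> np.ndarray:
    """Plain global histogram equalization onto [0, g_max]."""
    mapping, edges = _hist_mapping(image.ravel(), n_bins, clip_limit=None, g_max=g_max)
    idx = _bin_index(image, edges, n_bins)
    return mapping[idx]


def _bin_index(image: np.ndarray, edges: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.searchsorted(edges, image, side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def _hist_mapping(values: np.ndarray, n_bins: int, clip_limit: float | None,
                  g_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-equalization gray-level mapping with optional slope clipping.

    Clipping limits each bin to clip_limit times the mean bin count and
    redistributes the excess uniformly, bounding the slope of the transfer
    function and hence noise amplification.
    """
    lo, hi = 0.0, max(float(values.max()), 1e-12) if values.size else 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(values, bins=edges)
    hist = hist.astype(np.float64)
    if clip_limit is not None:
        limit = clip_limit * hist.mean()
        excess = np.clip(hist - limit, 0, None).sum()
        hist = np.minimum(hist, limit) + excess / n_bins
    cdf = np.cumsum(hist)
    if cdf[-1] <= 0:
        return np.linspace(0, g_max, n_bins), edges
    mapping = cdf / cdf[-1] * g_max
    return mapping, edges


def clahe(image: np.ndarray, clip_limit: float = 4.0,
          tile_grid: tuple[int, int] = (8, 8), n_bins: int = 256,
          g_max: float = 255.0) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``tile_grid`` contextual regions; each region
    gets a clipped-histogram equalization mapping, and every pixel is
    remapped by bilinear interpolation between the mappings of the four
    surrounding tile centers:

        s' = (1-y)((1-x) g_A(s) + x g_B(s)) + y((1-x) g_C(s) + x g_D(s))

    where x, y are the pixel's normalized distances to tile center A. With a
    single tile and no clipping this reduces to global equalization.
    """
    ny, nx = int(tile_grid[1]), int(tile_grid[0])
    h, w = image.shape
    if h // ny < 2 or w // nx < 2:
        raise ValueError("tiles must be at least 2x2 px")
    image = image.astype(np.float64)
    # shared bin edges so tile mappings are commensurable
    hi = max(float(image.max()), 1e-12)
    edges = np.linspace(0.0, hi, n_bins + 1)
    idx = _bin_index(image, edges, n_bins)

    row_bounds = np.linspace(0, h, ny + 1).astype(int)
    col_bounds = np.linspace(0, w, nx + 1).astype(int)
    maps = np.empty((ny, nx, n_bins))
    for i in range(ny):
        for j in range(nx):
            tile = idx[row_bounds[i]:row_bounds[i + 1], col_bounds[j]:col_bounds[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=n_bins).astype(np.float64)
            limit = clip_limit * hist.mean()
            excess = np.clip(hist - limit, 0, None).sum()
            hist = np.minimum(hist, limit) + excess / n_bins
            cdf = np.cumsum(hist)
            maps[i, j] = cdf / cdf[-1] * g_max if cdf[-1] > 0 else np.linspace(0, g_max, n_bins)

    centers_r = (row_bounds[:-1] + row_bounds[1:]) / 2.0
    centers_c = (col_bounds[:-1] + col_bounds[1:]) / 2.0
    rr = np.arange(h, dtype=np.float64)
    cc = np.arange(w, dtype=np.float64)
    # tile-center interval and normalized distance per axis (clamped at borders)
    i0 = np.clip(np.searchsorted(centers_r, rr) - 1, 0, ny - 1)
    i1 = np.minimum(i0 + 1, ny - 1)
    j0 = np.clip(np.searchsorted(centers_c, cc) - 1, 0, nx - 1)
    j1 = np.minimum(j0 + 1, nx - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(i1 > i0, (rr - centers_r[i0]) / (centers_r[i1] - centers_r[i0]), 0.0)
        x = np.where(j1 > j0, (cc - centers_c[j0]) / (centers_c[j1] - centers_c[j0]), 0.0)
    y = np.clip(y, 0.0, 1.0)[:, None]
    x = np.clip(x, 0.0, 1.0)[None, :]

    ga = maps[i0[:, None], j0[None, :], idx]
    gb = maps[i0[:, None], j1[None, :], idx]
    gc = maps[i1[:, None], j0[None, :], idx]
    gd = maps[i1[:, None], j1[None, :], idx]
    return (1 - y) * ((1 - x) * ga + x * gb) + y * ((1 - x) * gc + x * gd)


# ---------------------------------------------------------------------------
# Steger principal-curvature line detection
# ---------------------------------------------------------------------------

def steger_detect(image: np.ndarray, sigma: float, high_thresh: float,
                  low_thresh: float, dark_lines: bool = True) -> list[LinePoint]:
    """Subpixel curvilinear line points by principal-curvature analysis.

    ``image`` is analyzed at scale ``sigma`` (Gaussian derivative kernels).
    For dark lines on a bright background the sign convention is flipped by
    inverting the image. Hysteresis on the second-derivative magnitude keeps
    strong points (>= high) plus weaker points (>= low) connected to them.
    Width is measured by locating the gradient-magnitude maxima along the
    normal on both sides (capped at 2.5 sigma each side when no edge is
    found) and corrected for the detection-scale broadening of a
    Gaussian line profile.
    """
    if sigma <= 0.5:
        raise ValueError("sigma must exceed 0.5 px")
    if not high_thresh >= low_thresh >= 0:
        raise ValueError("need high_thresh >= low_thresh >= 0")
    img = np.asarray(image, dtype=np.float64)
    if img.max() > img.min():
        img = (img - img.min()) / (img.max() - img.min())
    if dark_lines:
        img = 1.0 - img    # detect as bright ridges

    gf = ndimage.gaussian_filter
    rr = gf(img, sigma, order=(1, 0), mode="nearest")
    rc = gf(img, sigma, order=(0, 1), mode="nearest")
    rrr = gf(img, sigma, order=(2, 0), mode="nearest")
    rrc = gf(img, sigma, order=(1, 1), mode="nearest")
    rcc = gf(img, sigma, order=(0, 2), mode="nearest")

    # eigenvalue of largest magnitude of [[rrr, rrc], [rrc, rcc]]
    tr = rrr + rcc
    det = rrr * rcc - rrc ** 2
    disc = np.sqrt(np.maximum((rrr - rcc) ** 2 / 4 + rrc ** 2, 0.0))
    lam1 = tr / 2 - disc          # most negative eigenvalue (ridge strength)
    # eigenvector for lam1: two algebraic forms, take the better-conditioned one
    va_r, va_c = rrc, lam1 - rrr
    vb_r, vb_c = lam1 - rcc, rrc
    use_b = np.hypot(vb_r, vb_c) > np.hypot(va_r, va_c)
    nr = np.where(use_b, vb_r, va_r)
    nc = np.where(use_b, vb_c, va_c)
    norm = np.hypot(nr, nc)
    degenerate = norm < 1e-12     # isotropic Hessian: orientation undefined
    nr = np.where(degenerate, 1.0, nr / np.where(degenerate, 1.0, norm))
    nc = np.where(degenerate, 0.0, nc / np.where(degenerate, 1.0, norm))

    response = np.maximum(-lam1, 0.0)    # bright ridge: lam1 < 0
    # subpixel offset along the normal where directional derivative vanishes
    denom = rrr * nr ** 2 + 2 * rrc * nr * nc + rcc * nc ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(rr * nr + rc * nc) / denom
    inside = (np.abs(t * nr) <= 0.5) & (np.abs(t * nc) <= 0.5) & np.isfinite(t)
    candidate = inside & (response >= low_thresh) & (lam1 < 0)

    # hysteresis on candidate pixels
    strong = candidate & (response >= high_thresh)
    labels, n_lab = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n_lab == 0:
        return []
    keep_label = np.zeros(n_lab + 1, dtype=bool)
    keep_label[np.unique(labels[strong])] = True
    keep_label[0] = False
    accepted = keep_label[labels]

    rows, cols = np.nonzero(accepted)
    if rows.size == 0:
        return []
    sub_r = rows + t[rows, cols] * nr[rows, cols]
    sub_c = cols + t[rows, cols] * nc[rows, cols]
    angles = np.mod(np.arctan2(nc[rows, cols], nr[rows, cols]), np.pi)

    widths = _measure_widths(img, sigma, sub_r, sub_c,
                             nr[rows, cols], nc[rows, cols])
    resp = response[rows, cols]
    return [LinePoint(r, c, a, w, s) for r, c, a, w, s
            in zip(sub_r, sub_c, angles, widths, resp)]


def _measure_widths(img: np.ndarray, sigma: float, rows: np.ndarray,
                    cols: np.ndarray, nr: np.ndarray, nc: np.ndarray) -> np.ndarray:
    """Edge-based width per line point, corrected for scale broadening.

    The gradient magnitude (at scale sigma) is sampled along the normal on
    both sides; the distance between its maxima is the raw width. A Gaussian
    line of intrinsic scale s appears with edges at +-sqrt(s^2 + sigma^2),
    so the raw half-width d is deconvolved as s = sqrt(max(d^2 - sigma^2, eps))
    and reported as the profile FWHM 2.355 s, which is nearly independent
    of the detection scale.
    """
    gr = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    gc = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    grad = np.hypot(gr, gc)
    max_d = 2.5 * sigma
    steps = np.linspace(0.25, max_d, max(8, int(max_d * 4)))
    half = np.empty((2, len(rows)))
    for side, sgn in enumerate((1.0, -1.0)):
        coords = np.stack([
            rows[None, :] + sgn * steps[:, None] * nr[None, :],
            cols[None, :] + sgn * steps[:, None] * nc[None, :],
        ])
        prof = ndimage.map_coordinates(grad, coords.reshape(2, -1), order=1,
                                       mode="nearest").reshape(len(steps), -1)
        half[side] = steps[np.argmax(prof, axis=0)]
    raw_half = half.mean(axis=0)
    s_line = np.sqrt(np.maximum(raw_half ** 2 - sigma ** 2, 0.05))
    return 2.355 * s_line


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def smooth_polyline(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average along a polyline, window shrinking at the ends.

    Sub-pixel localization noise makes linked centerlines zigzag; the
    zigzag inflates arclength (and everything derived from it) by several
    percent, so polylines are smoothed before geometry is measured.
    """
    n = len(points)
    half = window // 2
    out = np.empty_like(points, dtype=np.float64)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = points[i - k:i + k + 1].mean(axis=0)
    return out


def _angle_diff(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Difference between undirected orientations, in [0, pi/2]."""
    d = np.abs(np.mod(a - b, np.pi))
    return np.minimum(d, np.pi - d)


def link_line_points(points: list[LinePoint], h: float, l: float,
                     min_length: float = 10.0) -> list[list[LinePoint]]:
    """Chain line points into maximal polylines.

    Starting from the strongest unused point, the chain is extended in both
    tangent directions; among unused candidates within distance ``l`` whose
    normal differs by less than ``h`` and which lie in the forward
    half-plane, the one minimizing a combined distance/angle cost is chosen
    (at junctions this picks the continuation of minimal angle difference).
    Polylines shorter than ``min_length`` px of arclength are dropped.
    """
    if not 0 < h <= np.pi / 2:
        raise ValueError("h must lie in (0, pi/2]")
    if l <= 0:
        raise ValueError("l must be > 0")
    if not points:
        return []
    pos = np.array([[p.row, p.col] for p in points])
    ang = np.array([p.normal_angle for p in points])
    resp = np.array([p.response for p in points])
    tree = cKDTree(pos)
    used = np.zeros(len(points), dtype=bool)
    order = np.argsort(-resp)

    def grow(start: int, direction: np.ndarray) -> list[int]:
        chain: list[int] = []
        cur, d = start, direction
        while True:
            cand = [j for j in tree.query_ball_point(pos[cur], l) if not used[j]]
            if not cand:
                break
            cand = np.array(cand)
            vec = pos[cand] - pos[cur]
            dist = np.linalg.norm(vec, axis=1)
            fwd = (vec @ d) > 1e-9
            adiff = _angle_diff(ang[cand], ang[cur])
            ok = fwd & (adiff < h) & (dist > 1e-9)
            if not ok.any():
                break
            cost = dist[ok] / l + adiff[ok] / h
            nxt = cand[ok][np.argmin(cost)]
            used[nxt] = True
            chain.append(nxt)
            d = pos[nxt] - pos[cur]
            d = d / np.linalg.norm(d)
            cur = nxt
        return chain

    polylines = []
    for start in order:
        if used[start]:
            continue
        used[start] = True
        tangent = np.array([-np.sin(ang[start]), np.cos(ang[start])])
        forward = grow(start, tangent)
        backward = grow(start, -tangent)
        idx = backward[::-1] + [start] + forward
        if len(idx) < 2:
            continue
        smoothed = smooth_polyline(pos[idx])
        arclen = np.sum(np.linalg.norm(np.diff(smoothed, axis=0), axis=1))
        if arclen >= min_length:
            line = []
            for (r, c), i in zip(smoothed, idx):
                p = points[i]
                line.append(LinePoint(r, c, p.normal_angle, p.width, p.response))
            polylines.append(line)
    return polylines


def _outward_dir(pts: np.ndarray, end: int, k: int = 6) -> np.ndarray:
    """Unit vector pointing out of the polyline at the given end (0 or 1)."""
    k = min(k, len(pts) - 1)
    d = pts[0] - pts[k] if end == 0 else pts[-1] - pts[-1 - k]
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([0.0, 1.0])


def chain_fragments(polylines: list[np.ndarray], max_dist: float,
                    max_angle: float) -> list[list[tuple[int, bool]]]:
    """Group polyline fragments into chains by collinear endpoint matching.

    Any end of any fragment may connect to any end of another if the
    endpoint gap is at most ``max_dist`` px and both outward end directions
    align with the gap within ``max_angle`` rad. Joins are applied
    lowest-cost first, each end is used at most once, and joins that would
    close a cycle are rejected. Returns chains as ordered lists of
    (fragment index, reversed) pairs; callers concatenate the geometry.
    """
    n = len(polylines)
    if n == 0:
        return []
    endpos = [(p[0], p[-1]) for p in polylines]
    outdir = [(_outward_dir(p, 0), _outward_dir(p, 1)) for p in polylines]
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            for ei in (0, 1):
                for ej in (0, 1):
                    gap = endpos[j][ej] - endpos[i][ei]
                    dist = np.linalg.norm(gap)
                    if dist > max_dist or dist == 0:
                        continue
                    gd = gap / dist
                    a1 = np.arccos(np.clip(outdir[i][ei] @ gd, -1, 1))
                    a2 = np.arccos(np.clip(outdir[j][ej] @ -gd, -1, 1))
                    if a1 < max_angle and a2 < max_angle:
                        cost = dist / max_dist + (a1 + a2) / max_angle
                        candidates.append((cost, i, ei, j, ej))

    used: set[tuple[int, int]] = set()
    parent = list(range(n))           # union-find over fragments

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    links: dict[tuple[int, int], tuple[int, int]] = {}
    for cost, i, ei, j, ej in sorted(candidates):
        if (i, ei) in used or (j, ej) in used or find(i) == find(j):
            continue
        used.add((i, ei))
        used.add((j, ej))
        links[(i, ei)] = (j, ej)
        links[(j, ej)] = (i, ei)
        parent[find(i)] = find(j)

    chains, visited = [], set()
    for i in range(n):
        if i in visited:
            continue
        if (i, 0) in links and (i, 1) in links:
            continue  # interior fragment, reached from its chain's end
        chain, frag, entry_end = [], i, 0 if (i, 0) not in links else 1
        while True:
            visited.add(frag)
            # enter at entry_end, exit at the other end
            chain.append((frag, entry_end == 1))
            nxt = links.get((frag, 1 - entry_end))
            if nxt is None:
                break
            frag, entry_end = nxt
        chains.append(chain)
    return chains


def suppress_overlapping_lines(lines: list[list[LinePoint]],
                               overlap_fraction: float = 0.6) -> list[list[LinePoint]]:
    """Drop centerlines that duplicate an already-kept, longer line.

    Shoulder ridges and tile artifacts can yield a second centerline running
    parallel to a vessel within its own width. Lines are kept longest-first;
    a line is discarded when more than ``overlap_fraction`` of its points lie
    within the local half-width of a kept line.
    """
    def arclen(line):
        pts = np.array([[p.row, p.col] for p in line])
        return np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))

    kept: list[list[LinePoint]] = []
    kept_pts: list[np.ndarray] = []
    kept_half: list[np.ndarray] = []
    for line in sorted(lines, key=arclen, reverse=True):
        pts = np.array([[p.row, p.col] for p in line])
        if kept:
            all_pts = np.vstack(kept_pts)
            all_half = np.concatenate(kept_half)
            tree = cKDTree(all_pts)
            dists, idx = tree.query(pts)
            frac = np.mean(dists <= np.maximum(all_half[idx], 1.0))
            if frac > overlap_fraction:
                continue
        kept.append(line)
        kept_pts.append(pts)
        kept_half.append(np.array([max(p.width, 2.0) / 2 for p in line]))
    return kept


def merge_polylines(lines: list[list[LinePoint]], max_dist: float,
                    max_angle: float) -> list[list[LinePoint]]:
    """Merge vessel centerline fragments that continue one another.

    Plasma gaps and local contrast dips can split one vessel into several
    centerline pieces; merging restores the full length, on which both the
    density metrics and the per-vessel velocity ceiling v_max depend.
    """
    coords = [np.array([[p.row, p.col] for p in line]) for line in lines]
    chains = chain_fragments(coords, max_dist, max_angle)
    out = []
    for chain in chains:
        merged: list[LinePoint] = []
        for idx, rev in chain:
            merged.extend(lines[idx][::-1] if rev else lines[idx])
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# the two-pass detector
# ---------------------------------------------------------------------------

def _centerline_contrast(image: np.ndarray, line: list[LinePoint]) -> float:
    """Mean flank-minus-centerline intensity (gray levels) along a line.

    Sampled on the raw mean image at +-1.5 local widths along each point's
    normal; positive values mean the line is darker than its surroundings,
    as a hemoglobin-absorbing vessel must be.
    """
    pts = np.array([[p.row, p.col] for p in line])
    nr = np.cos([p.normal_angle for p in line])
    nc = np.sin([p.normal_angle for p in line])
    off = np.array([max(p.width, 2.0) * 1.5 for p in line])
    center = ndimage.map_coordinates(image, pts.T, order=1, mode="nearest")
    left = ndimage.map_coordinates(
        image, (pts + np.column_stack([off * nr, off * nc])).T,
        order=1, mode="nearest")
    right = ndimage.map_coordinates(
        image, (pts - np.column_stack([off * nr, off * nc])).T,
        order=1, mode="nearest")
    return float(((left + right) / 2 - center).mean())


def classify_vessel_type(mean_diameter_um: float,
                         capillary_max_diameter_um: float = 20.0) -> str:
    """Capillary iff mean diameter <= 20 um (boundary inclusive), else venule."""
    if mean_diameter_um <= 0:
        raise ValueError("mean diameter must be > 0")
    return "capillary" if mean_diameter_um <= capillary_max_diameter_um else "venule"


def detect_vessels(mean_image: np.ndarray, pixel_pitch: float,
                   config: AnalysisConfig | None = None) -> list[VesselSegment]:
    """Two-pass vessel detection on the mean image.

    The capillary pass runs at full resolution with a small scale; the
    venule pass runs on a decimated copy with a larger scale so vessels up
    to a few hundred micrometers stay detectable. Each pass applies CLAHE
    first. Venule-pass line points within one local vessel width of a
    capillary-pass centerline point are eliminated before linking, so a
    vessel found by both passes yields one segment.
    """
    config = config or AnalysisConfig()

    cap_img = clahe(mean_image, config.clahe_clip, config.clahe_tiles)
    cap_points = steger_detect(cap_img, config.sigma_capillary,
                               config.steger_high, config.steger_low)
    cap_lines = link_line_points(cap_points, config.link_h, config.link_l,
                                 config.min_centerline_px)
    cap_lines = merge_polylines(cap_lines, config.vessel_merge_dist,
                                config.vessel_merge_angle)
    cap_lines = suppress_overlapping_lines(cap_lines)

    ds = config.venule_downsample
    ven_src = ndimage.gaussian_filter(mean_image, ds / 2.0)[::ds, ::ds]
    ven_img = clahe(ven_src, config.clahe_clip, config.clahe_tiles)
    ven_points = steger_detect(ven_img, config.sigma_venule,
                               config.steger_high_venule, config.steger_low_venule)
    # back to full-resolution pixel coordinates
    for p in ven_points:
        p.row *= ds
        p.col *= ds
        p.width *= ds

    kept_cap = [p for line in cap_lines for p in line]
    if kept_cap and ven_points:
        cap_tree = cKDTree([[p.row, p.col] for p in kept_cap])
        cap_widths = np.array([max(p.width, 1.0) for p in kept_cap])
        dists, idx = cap_tree.query([[p.row, p.col] for p in ven_points])
        ven_points = [p for p, d, i in zip(ven_points, dists, idx)
                      if d > cap_widths[i]]
    ven_lines = link_line_points(ven_points, config.link_h, config.link_l * ds,
                                 config.min_centerline_px)
    ven_lines = merge_polylines(ven_lines, config.vessel_merge_dist * ds,
                                config.vessel_merge_angle)

    segments: list[VesselSegment] = []
    next_id = 0
    for line, min_width_px, min_contrast in (
            [(ln, 2.0, config.min_vessel_contrast) for ln in cap_lines]
            + [(ln, 2.0 * ds, config.min_venule_contrast) for ln in ven_lines]):
        seg = VesselSegment(id=next_id, centerline=line, pixel_pitch=pixel_pitch)
        # widths below each pass's resolution cannot be vessels (speckle/texture)
        if seg.length <= 0 or seg.mean_diameter < min_width_px * pixel_pitch:
            continue
        # absorbance check on the raw mean image: a vessel must be darker
        # than its flanks; contrast-stretch ridges in near-flat regions and
        # shallow texture valleys fail
        if _centerline_contrast(mean_image, line) < min_contrast:
            continue
        seg.vessel_type = classify_vessel_type(seg.mean_diameter,
                                               config.capillary_max_diameter_um)
        seg.id = next_id
        segments.append(seg)
        next_id += 1
    return segments
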