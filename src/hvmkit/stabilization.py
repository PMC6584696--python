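"""Video stabilization by sparse optical flow and similarity registration.

Camera shake in handheld recordings is estimated by tracking corner
features between consecutive frames with a pyramidal Lucas-Kanade tracker,
robust-fitting a similarity transform (translation, rotation, scale) per
frame pair, and accumulating to a camera trajectory. The trajectory is
smoothed with a centered moving average so that slow physiological panning
is preserved while jitter is removed; only the residual (raw minus
smoothed) is corrected. Frames are then warped and cropped to the common
valid region, and the field of view is recomputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.transform import SimilarityTransform, warp

from .config import AnalysisConfig
from .io import ImageSequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameTransform:
    """Similarity transform p' = scale * R(theta) @ p + (tx, ty), in (x, y) = (col, row)."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @classmethod
    def identity(cls) -> "FrameTransform":
        return cls()

    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([
            [self.scale * c, -self.scale * s, self.tx],
            [self.scale * s, self.scale * c, self.ty],
            [0.0, 0.0, 1.0],
        ])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "FrameTransform":
        scale = math.hypot(m[0, 0], m[1, 0])
        return cls(tx=m[0, 2], ty=m[1, 2], theta=math.atan2(m[1, 0], m[0, 0]), scale=scale)

    def compose(self, other: "FrameTransform") -> "FrameTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return FrameTransform.from_matrix(self.matrix() @ other.matrix())

    def inverse(self) -> "FrameTransform":
        return FrameTransform.from_matrix(np.linalg.inv(self.matrix()))

    def as_skimage(self) -> SimilarityTransform:
        return SimilarityTransform(matrix=self.matrix())

    def is_near_identity(self, tol: float = 1e-6) -> bool:
        return (abs(self.tx) < tol and abs(self.ty) < tol
                and abs(self.theta) < tol and abs(self.scale - 1) < tol)


# ---------------------------------------------------------------------------
# sparse pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------

def _detect_corners(img: np.ndarray, max_features: int, min_distance: int,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Shi-Tomasi (minimum-eigenvalue) corners, (N, 2) as (row, col).

    ``mask`` restricts corners to static tissue: corners on flowing red
    blood cells are strong but track the flow, not the camera.
    """
    response = corner_shi_tomasi(img, sigma=2)
    if mask is not None:
        response = np.where(mask, response, 0.0)
    peaks = corner_peaks(response, min_distance=min_distance,
                         threshold_rel=0.0, num_peaks=max_features)
    return peaks.astype(np.float64)


def _static_mask(frames: np.ndarray, quantile: float = 0.5) -> np.ndarray:
    """Temporally quiet pixels: low per-pixel variance marks static tissue."""
    var = frames.var(axis=0)
    return var <= np.quantile(var, quantile)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img.astype(np.float64)]
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(pyr[-1], 1.0)
        pyr.append(smoothed[::2, ::2])
    return pyr


def track_features(
    img0: np.ndarray,
    img1: np.ndarray,
    pts: np.ndarray,
    window: int = 21,
    levels: int = 3,
    iterations: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Track (row, col) points from img0 to img1.

    Returns (tracked points (N, 2), validity mask (N,)). Implements the
    iterative coarse-to-fine Lucas-Kanade scheme; all features are solved
    simultaneously via vectorized window sampling.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    n = len(pts)
    if n == 0:
        return pts.copy(), np.zeros(0, dtype=bool)
    half = window // 2
    off = np.arange(-half, half + 1, dtype=np.float64)
    orow, ocol = np.meshgrid(off, off, indexing="ij")
    offsets = np.stack([orow.ravel(), ocol.ravel()])        # (2, W*W)

    pyr0 = _pyramid(img0, levels)
    pyr1 = _pyramid(img1, levels)
    disp = np.zeros((n, 2))
    valid = np.ones(n, dtype=bool)

    for level in range(levels - 1, -1, -1):
        im0, im1 = pyr0[level], pyr1[level]
        gy, gx = np.gradient(im0)
        p = pts / 2 ** level                                 # (N, 2) row, col
        coords0 = p.T[:, :, None] + offsets[:, None, :]      # (2, N, W*W)
        patch0 = ndimage.map_coordinates(im0, coords0.reshape(2, -1), order=1,
                                         mode="nearest").reshape(n, -1)
        ix = ndimage.map_coordinates(gx, coords0.reshape(2, -1), order=1,
                                     mode="nearest").reshape(n, -1)
        iy = ndimage.map_coordinates(gy, coords0.reshape(2, -1), order=1,
                                     mode="nearest").reshape(n, -1)
        # 2x2 structure matrix per feature, (row, col) ordering
        a = (iy * iy).sum(1)
        b = (iy * ix).sum(1)
        c = (ix * ix).sum(1)
        det = a * c - b * b
        valid &= det > 1e-6
        det = np.where(det > 1e-6, det, 1.0)

        for _ in range(iterations):
            coords1 = (p + disp).T[:, :, None] + offsets[:, None, :]
            patch1 = ndimage.map_coordinates(im1, coords1.reshape(2, -1), order=1,
                                             mode="nearest").reshape(n, -1)
            err = patch0 - patch1
            b1 = (err * iy).sum(1)
            b2 = (err * ix).sum(1)
            drow = (c * b1 - b * b2) / det
            dcol = (a * b2 - b * b1) / det
            step = np.stack([drow, dcol], axis=1)
            disp += np.where(valid[:, None], step, 0.0)
            if np.max(np.abs(step[valid])) < 0.01 if valid.any() else True:
                break
        if level > 0:
            disp *= 2.0

    tracked = pts + disp
    h, w = img1.shape
    inside = ((tracked[:, 0] >= half) & (tracked[:, 0] < h - half)
              & (tracked[:, 1] >= half) & (tracked[:, 1] < w - half))
    return tracked, valid & inside


def _robust_similarity(src_rc: np.ndarray, dst_rc: np.ndarray,
                       prior_rc: np.ndarray | None = None,
                       gate: float = 3.0) -> FrameTransform | None:
    """Fit dst = T(src) with outlier rejection; coords (row, col).

    Correspondences are first gated against a displacement prior (the
    componentwise median by default): moving red blood cells produce
    coherent but non-camera motion that must not enter the fit. A second
    MAD-based pass tightens the inlier set around the fitted transform.
    """
    src = src_rc[:, ::-1]   # -> (x, y)
    dst = dst_rc[:, ::-1]
    disp = dst - src
    center = prior_rc[::-1] if prior_rc is not None else np.median(disp, axis=0)
    res = np.linalg.norm(disp - center, axis=1)
    keep = res <= gate
    if keep.sum() < 3:
        return None
    tf = SimilarityTransform.from_estimate(src[keep], dst[keep])
    if not tf:
        return None
    res2 = np.linalg.norm(tf(src[keep]) - dst[keep], axis=1)
    mad2 = np.median(np.abs(res2 - np.median(res2)))
    keep2 = res2 <= max(3 * 1.4826 * mad2, 0.3)
    if keep2.sum() >= 3 and keep2.sum() < keep.sum():
        tf2 = SimilarityTransform.from_estimate(src[keep][keep2], dst[keep][keep2])
        if tf2:
            tf = tf2
    return FrameTransform.from_matrix(tf.params)


def estimate_transforms(seq: ImageSequence, config: AnalysisConfig | None = None) -> list[FrameTransform]:
    """Cumulative camera trajectory: transform of each frame into frame-0 coordinates.

    Corners are re-detected in every frame and tracked to the next; a robust
    similarity fit per pair is accumulated. Pairs with too few tracked
    features inherit the previous pair transform.
    """
    config = config or AnalysisConfig()
    frames = seq.as_float()
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames")

    # corners on flowing cells follow the blood, not the camera; restrict
    # the feature set to temporally quiet (static-tissue) pixels
    mask = _static_mask(frames)

    cumulative = [FrameTransform.identity()]
    prev_pair = FrameTransform.identity()
    for t in range(1, n):
        pair = None
        corners = _detect_corners(frames[t - 1], config.stab_max_features,
                                  config.stab_min_distance, mask)
        if len(corners) >= config.stab_min_features:
            tracked, ok = track_features(frames[t - 1], frames[t], corners,
                                         window=config.stab_window,
                                         levels=config.stab_pyr_levels,
                                         iterations=config.stab_iterations)
            if ok.sum() >= config.stab_min_features:
                # correspondences frame-t -> frame-(t-1)
                pair = _robust_similarity(tracked[ok], corners[ok])
                if pair is not None and (
                        math.hypot(pair.tx, pair.ty) > config.stab_max_shift
                        or abs(pair.theta) > 0.1):
                    log.warning("frame %d: implausible motion estimate, "
                                "inheriting previous transform", t)
                    pair = None
        if pair is None:
            log.warning("frame %d: too few features, inheriting previous transform", t)
            pair = prev_pair
        prev_pair = pair
        cumulative.append(cumulative[-1].compose(pair))
    return cumulative


# ---------------------------------------------------------------------------
# trajectory smoothing and warping
# ---------------------------------------------------------------------------

def smooth_trajectory(transforms: list[FrameTransform], window: int) -> list[FrameTransform]:
    """Centered moving average of trajectory parameters (tx, ty, theta, log scale).

    The window shrinks symmetrically near the sequence ends so a linear
    drift passes through unchanged in the interior.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    n = len(transforms)
    if window > n:
        log.warning("smoothing window %d > %d frames, clamping", window, n)
        window = n if n % 2 == 1 else n - 1
        window = max(window, 1)
    params = np.array([[t.tx, t.ty, t.theta, math.log(t.scale)] for t in transforms])
    half = window // 2
    out = np.empty_like(params)
    for i in range(n):
        k = min(half, i, n - 1 - i)     # symmetric shrink keeps linear trends
        out[i] = params[i - k:i + k + 1].mean(axis=0)
    return [FrameTransform(tx, ty, th, math.exp(ls)) for tx, ty, th, ls in out]


def correction_transforms(raw: list[FrameTransform],
                          smoothed: list[FrameTransform]) -> list[FrameTransform]:
    """Per-frame correction smoothed^-1 ∘ raw: removes jitter, keeps slow drift."""
    return [s.inverse().compose(r) for r, s in zip(raw, smoothed)]


def apply_and_crop(seq: ImageSequence, transforms: list[FrameTransform]) -> ImageSequence:
    """Warp each frame by its correction and crop to the common valid region.

    Out-of-frame pixels introduced by warping are tracked with a validity
    mask; the output is the largest axis-aligned rectangle valid in every
    frame, and the field-of-view area follows the cropped size.
    """
    if len(transforms) != seq.n_frames:
        raise ValueError("one transform per frame required")
    frames = seq.as_float()
    h, w = seq.shape
    warped = np.empty_like(frames)
    mask = np.ones((h, w), dtype=bool)
    ones = np.ones((h, w))
    for i, (frame, tf) in enumerate(zip(frames, transforms)):
        if tf.is_near_identity():
            warped[i] = frame
            continue
        inv = tf.inverse().as_skimage()
        warped[i] = warp(frame, inv, order=1, mode="constant", cval=-1.0,
                         preserve_range=True)
        valid = warp(ones, inv, order=1, mode="constant", cval=0.0,
                     preserve_range=True) > 0.999
        mask &= valid

    top, bottom, left, right = 0, h, 0, w
    while top < bottom and left < right:
        sub = mask[top:bottom, left:right]
        if sub.all():
            break
        candidates = [
            ((~sub[0, :]).sum(), "top"),
            ((~sub[-1, :]).sum(), "bottom"),
            ((~sub[:, 0]).sum(), "left"),
            ((~sub[:, -1]).sum(), "right"),
        ]
        _, side = max(candidates)
        if side == "top":
            top += 1
        elif side == "bottom":
            bottom -= 1
        elif side == "left":
            left += 1
        else:
            right -= 1
    if bottom - top < 8 or right - left < 8:
        raise RuntimeError("stabilization failed, excessive motion")

    cropped = warped[:, top:bottom, left:right]
    cropped = np.clip(cropped, 0, None)
    return seq.copy_with(cropped.astype(seq.frames.dtype)
                         if np.issubdtype(seq.frames.dtype, np.integer)
                         else cropped)


def stabilize(seq: ImageSequence, config: AnalysisConfig | None = None
              ) -> tuple[ImageSequence, list[FrameTransform]]:
    """Full stabilization: estimate, smooth, correct, crop."""
    config = config or AnalysisConfig()
    raw = estimate_transforms(seq, config)
    smoothed = smooth_trajectory(raw, config.smoothing_window)
    corrections = correction_transforms(raw, smoothed)
    return apply_and_crop(seq, corrections), raw
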