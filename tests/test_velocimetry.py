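import numpy as np
import pytest

from hvmkit.config import AnalysisConfig
from hvmkit.detection import compute_mean_image, detect_vessels
from hvmkit.io import ImageSequence
from hvmkit.velocimetry import (RBCPath, SpaceTimeDiagram, analyze_vessel,
                                build_space_time_diagram, classify_paths,
                                classify_perfusion, compute_vmax,
                                curvature_index, detect_rbc_paths,
                                enhance_frames, path_velocity, vessel_rbcv)


def _path(pts, **kw):
    p = RBCPath(points=np.asarray(pts, dtype=np.float64))
    for k, v in kw.items():
        setattr(p, k, v)
    return p


# ---------------------------------------------------------------------------
# per-frame enhancement
# ---------------------------------------------------------------------------

class TestEnhanceFrames:
    def test_flicker_suppressed(self, rng):
        base = rng.normal(150, 20, (64, 64)).clip(0, 255)
        flicker = np.where(np.arange(10) % 2 == 0, 20.0, -20.0)
        frames = np.stack([(base + f).clip(0, 255) for f in flicker])
        seq = ImageSequence(frames, 25, 1.0)
        out = enhance_frames(seq, smooth_sigma=0.0).as_float()
        means = out.mean(axis=(1, 2))
        assert np.ptp(means) < 2.0

    def test_smoothing_variance_response(self, rng):
        """Gaussian smoothing cuts iid-noise variance by ~1/(4 pi s^2)."""
        frames = rng.normal(128, 12, (3, 256, 256)).clip(0, 255)
        seq = ImageSequence(frames, 25, 1.0)
        s = 3.0
        rough = enhance_frames(seq, smooth_sigma=0.0).as_float()
        smooth = enhance_frames(seq, smooth_sigma=s).as_float()
        ratio = smooth.var() / rough.var()
        assert ratio == pytest.approx(1.0 / (4 * np.pi * s ** 2), rel=0.3)


# ---------------------------------------------------------------------------
# diagram construction
# ---------------------------------------------------------------------------

class TestBuildDiagram:
    def test_static_scene_horizontal_banding(self, barcode_scene, config):
        seq, _ = barcode_scene
        vessels = detect_vessels(compute_mean_image(seq), seq.pixel_pitch, config)
        vessels.sort(key=lambda v: -v.length)
        enh = enhance_frames(seq, config.frame_smooth_sigma)
        std = build_space_time_diagram(enh, vessels[0])
        # each row constant over time (up to quantization/noise)
        row_ranges = np.ptp(std.matrix, axis=1)
        assert np.median(row_ranges) < 30.0

    def test_dimensions_follow_centerline_and_frames(self, straight_tube_scene,
                                                     config):
        seq, _ = straight_tube_scene
        vessels = detect_vessels(compute_mean_image(seq), seq.pixel_pitch, config)
        vessels.sort(key=lambda v: -v.length)
        enh = enhance_frames(seq, config.frame_smooth_sigma)
        std = build_space_time_diagram(enh, vessels[0])
        arclen_px = vessels[0].length / seq.pixel_pitch
        assert std.matrix.shape[1] == seq.n_frames
        assert std.matrix.shape[0] == pytest.approx(arclen_px, abs=2)

    def test_diagram_shape_validation(self):
        with pytest.raises(ValueError):
            SpaceTimeDiagram(np.zeros((1, 5)), 1.0, 25.0, 0)


# ---------------------------------------------------------------------------
# path detection on constructed diagrams
# ---------------------------------------------------------------------------

def _synthetic_diagram(slope_px_per_frame, s_len=120, t_len=60, line_sigma=2.0):
    """Bright field with dark lines of the given slope, one per 30 px."""
    ss, tt = np.mgrid[0:s_len, 0:t_len].astype(np.float64)
    img = np.full((s_len, t_len), 220.0)
    for offset in range(-int(slope_px_per_frame * t_len), s_len + 30, 30):
        d = ss - (offset + slope_px_per_frame * tt)
        img -= 140.0 * np.exp(-d ** 2 / (2 * line_sigma ** 2))
    return np.clip(img, 0, 255)


class TestDetectPaths:
    def test_uniform_diagram_no_paths(self, config):
        std = SpaceTimeDiagram(np.full((50, 40), 128.0), 1.0, 25.0, 0)
        assert detect_rbc_paths(std, config) == []

    def test_known_slope_recovered(self, config):
        # slope equivalent to 500 um/s at pitch 1.0, f 25: 20 px/frame is
        # steep; use pitch/f that map 4 px/frame to 500 um/s instead
        std = SpaceTimeDiagram(_synthetic_diagram(4.0), pixel_pitch=1.0,
                               frame_rate=125.0, vessel_id=0)
        paths = detect_rbc_paths(std, config)
        assert paths
        vels = [path_velocity(p, std.pixel_pitch, std.frame_rate)
                for p in paths if np.ptp(p.points[:, 1]) > 5]
        assert np.median(vels) == pytest.approx(500.0, rel=0.1)

    def test_barcode_diagram_near_zero_slope(self, config):
        std = SpaceTimeDiagram(_synthetic_diagram(0.0), 1.0, 25.0, 0)
        paths = detect_rbc_paths(std, config)
        assert paths
        for p in paths:
            if np.ptp(p.points[:, 1]) > 5:
                assert path_velocity(p, 1.0, 25.0) < 5.0


# ---------------------------------------------------------------------------
# per-path measures
# ---------------------------------------------------------------------------

class TestPathVelocity:
    def test_exact_line(self):
        p = _path([[4.0 * t, float(t)] for t in range(10)])
        assert path_velocity(p, 1.0, 25.0) == pytest.approx(100.0)

    def test_piecewise_mean_of_derivative(self):
        pts = [[2.0 * t, float(t)] for t in range(11)]
        pts += [[20.0 + 4.0 * (t - 10), float(t)] for t in range(11, 21)]
        p = _path(pts)
        # equal-duration halves at 200 and 400 um/s (pitch 100, f 1)
        assert path_velocity(p, 100.0, 1.0) == pytest.approx(300.0, rel=0.02)

    def test_reversed_direction_same_magnitude(self):
        fwd = _path([[4.0 * t, float(t)] for t in range(10)])
        rev = _path([[-4.0 * t, float(t)] for t in range(10)])
        assert path_velocity(fwd, 1.3, 25) == pytest.approx(
            path_velocity(rev, 1.3, 25))

    def test_zero_time_span_raises(self):
        p = _path([[0.0, 5.0], [10.0, 5.0]])
        with pytest.raises(ValueError):
            path_velocity(p, 1.0, 25.0)

    def test_agrees_with_least_squares_on_straight_tracks(self, rng):
        """Independent regression oracle within 5% on straight tracks."""
        for _ in range(20):
            slope = rng.uniform(0.5, 8.0)
            t = np.arange(0, 30.0)
            s = slope * t + rng.normal(0, 0.15, t.shape)
            p = _path(np.column_stack([s, t]))
            v = path_velocity(p, 1.0, 1.0)
            ls = abs(np.polyfit(t, s, 1)[0])
            assert v == pytest.approx(ls, rel=0.05)


class TestCurvatureIndex:
    def test_straight_path(self):
        assert curvature_index(_path([[t, t] for t in range(10)])) == pytest.approx(1.0)

    def test_semicircle(self):
        theta = np.linspace(0, np.pi, 200)
        pts = np.column_stack([10 * np.sin(theta), 10 - 10 * np.cos(theta)])
        assert curvature_index(_path(pts)) == pytest.approx(2 / np.pi, rel=0.01)

    def test_closed_loop(self):
        theta = np.linspace(0, 2 * np.pi, 300)
        pts = np.column_stack([10 * np.sin(theta), 10 * np.cos(theta)])
        assert curvature_index(_path(pts)) == pytest.approx(0.0, abs=1e-6)

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            curvature_index(_path([[1.0, 1.0]]))


class TestVmax:
    @pytest.mark.parametrize("l,f,expected", [(300.0, 25.0, 2500.0),
                                              (60.0, 60.0, 1200.0),
                                              (0.0, 25.0, 0.0)])
    def test_formula(self, l, f, expected):
        assert compute_vmax(l, f) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_vmax(-1.0, 25.0)
        with pytest.raises(ValueError):
            compute_vmax(100.0, 0.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyPaths:
    def test_short_path_is_artifact(self, config):
        p = _path([[0, 0], [1, 1], [2, 2]])
        out = classify_paths([p], 1.0, 25.0, v_max=1e6, config=config)
        assert out[0].path_type == "artifact"

    def test_overspeed_is_artifact(self, config):
        p = _path([[40.0 * t, float(t)] for t in range(30)])
        v = path_velocity(p, 1.0, 25.0)
        out = classify_paths([p], 1.0, 25.0, v_max=v / 1.2, config=config)
        assert out[0].path_type == "artifact"

    def test_curvy_path_is_artifact(self, config):
        t = np.linspace(0, 29, 60)
        s = 20 + 15 * np.sin(t / 2)
        out = classify_paths([_path(np.column_stack([s, t]))], 1.0, 25.0,
                             v_max=1e6, config=config)
        assert out[0].path_type == "artifact"

    def test_slow_path_is_no_low_flow(self, config):
        # 10 um/s with cutoff 25
        p = _path([[0.4 * t, float(t)] for t in range(40)])
        out = classify_paths([p], 1.0, 25.0, v_max=1e6, config=config)
        assert out[0].velocity == pytest.approx(10.0)
        assert out[0].path_type == "no_low_flow"

    def test_normal_path(self, config):
        p = _path([[4.0 * t, float(t)] for t in range(40)])
        out = classify_paths([p], 1.0, 25.0, v_max=1e6, config=config)
        assert out[0].path_type == "normal_flow"


class TestVesselRbcv:
    def test_mean_of_survivors(self):
        paths = [_path([[0, 0], [1, 1]], velocity=v, path_type="normal_flow")
                 for v in (100.0, 200.0, 300.0)]
        assert vessel_rbcv(paths) == pytest.approx(200.0)

    def test_single_path(self):
        p = _path([[0, 0], [1, 1]], velocity=250.0, path_type="normal_flow")
        assert vessel_rbcv([p]) == 250.0

    def test_all_artifacts_undefined(self):
        p = _path([[0, 0], [1, 1]], velocity=250.0, path_type="artifact")
        assert vessel_rbcv([p]) is None


def _population(n_normal, n_slow, v_normal=200.0, v_slow=5.0):
    mk = lambda v, t: _path([[0, 0], [1, 1]], velocity=v, path_type=t)
    return ([mk(v_normal, "normal_flow") for _ in range(n_normal)]
            + [mk(v_slow, "no_low_flow") for _ in range(n_slow)])


class TestClassifyPerfusion:
    def test_all_normal_is_perfused(self, config):
        assert classify_perfusion(_population(50, 0), config) == "perfused"

    def test_95_percent_boundary(self, config):
        assert classify_perfusion(_population(96, 4), config) == "perfused"
        assert classify_perfusion(_population(95, 5), config) == "non_perfused"

    def test_barcode_rule_overrides_fast_minority(self, config):
        """96% slow paths force non-perfused despite a fast minority."""
        pop = _population(4, 96, v_normal=800.0)
        assert classify_perfusion(pop, config) == "non_perfused"

    def test_no_paths_is_non_perfused(self, config):
        assert classify_perfusion([], config) == "non_perfused"

    def test_monotone_in_normal_fraction(self, config):
        """Raising the normal-flow fraction never flips perfused -> non."""
        states = [classify_perfusion(_population(k, 100 - k), config)
                  for k in range(80, 101)]
        seen_perfused = False
        for s in states:
            if s == "perfused":
                seen_perfused = True
            assert not (seen_perfused and s == "non_perfused")

    def test_normal_fit_mode(self):
        cfg = AnalysisConfig(perfusion_mode="normal_fit")
        pop = [_path([[0, 0], [1, 1]], velocity=v, path_type="normal_flow")
               for v in np.random.default_rng(0).normal(300, 30, 50)]
        assert classify_perfusion(pop, cfg) == "perfused"


# ---------------------------------------------------------------------------
# end-to-end per-vessel velocimetry
# ---------------------------------------------------------------------------

class TestAnalyzeVessel:
    def test_velocity_recovered_and_vmax_respected(self, straight_tube_scene,
                                                   config):
        seq, gt = straight_tube_scene
        vessels = detect_vessels(compute_mean_image(seq), seq.pixel_pitch, config)
        vessels.sort(key=lambda v: -v.length)
        enh = enhance_frames(seq, config.frame_smooth_sigma)
        paths = analyze_vessel(enh, vessels[0], config)
        assert vessels[0].rbcv == pytest.approx(300.0, rel=0.1)
        assert vessels[0].perfusion == "perfused"
        for p in paths:
            if p.path_type != "artifact":
                assert p.velocity <= vessels[0].v_max

    def test_barcode_vessel_non_perfused(self, barcode_scene, config):
        seq, _ = barcode_scene
        vessels = detect_vessels(compute_mean_image(seq), seq.pixel_pitch, config)
        vessels.sort(key=lambda v: -v.length)
        enh = enhance_frames(seq, config.frame_smooth_sigma)
        analyze_vessel(enh, vessels[0], config)
        assert vessels[0].perfusion == "non_perfused"
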