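import numpy as np
import pytest

from vesselmorph.graph import VesselGraph
from vesselmorph.io_qc import FundusFrame
from vesselmorph.morphometry import (
    MorphometryConfig,
    analyze_eye,
    bifurcation_angle,
    default_box_sizes,
    eye_tortuosity,
    fractal_dimension,
    segment_tortuosity,
    vessel_angle_mean,
    vessel_density,
)
from vesselmorph.roi import Circle, build_roi, mask_to_roi, mec_of_mask
from vesselmorph.synthetic import SynthParams, analytic_tortuosity_of_sinusoid, generate_tree


def _path(p0, p1, step=0.7):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(3, int(np.hypot(*(p1 - p0)) / step))
    return np.linspace(p0, p1, n)


def _star_graph(center, arm_tips):
    """Graph with one central node and straight arms to each tip."""
    g = VesselGraph()
    c = g.add_node([tuple(np.round(center).astype(int))])
    for tip in arm_tips:
        t = g.add_node([tuple(np.round(tip).astype(int))])
        g.add_edge(_path(center, tip), c, t)
    return g, c


class TestBifurcationAngle:
    def test_symmetric_y_measures_opening_angle(self):
        # daughters at +-30 deg about vertical-up, parent toward the OD below
        center = (100.0, 100.0)
        up = np.array([0.0, -1.0])
        d1 = np.array([np.sin(np.radians(30)), -np.cos(np.radians(30))])
        d2 = np.array([-np.sin(np.radians(30)), -np.cos(np.radians(30))])
        g, c = _star_graph(center, [center + 60 * d1, center + 60 * d2,
                                    center - 60 * up])
        assert bifurcation_angle(g, c, od_center=(100.0, 400.0)) == pytest.approx(60.0, abs=2.0)

    def test_t_junction_straight_plus_perpendicular(self):
        center = (100.0, 100.0)
        tips = [(100.0, 40.0),      # continues away from OD
                (160.0, 100.0),     # perpendicular branch
                (100.0, 160.0)]     # parent stem toward OD below
        g, c = _star_graph(center, tips)
        assert bifurcation_angle(g, c, od_center=(100.0, 400.0)) == pytest.approx(90.0, abs=2.0)

    def test_non_bifurcation_rejected(self):
        g, c = _star_graph((50.0, 50.0), [(50.0, 10.0), (90.0, 50.0)])
        with pytest.raises(ValueError, match="not a bifurcation"):
            bifurcation_angle(g, c, od_center=(50.0, 200.0))

    def test_mean_is_unweighted_average(self):
        g = VesselGraph()
        od = (0.0, 1000.0)
        for cx, opening in ((100.0, 50.0), (400.0, 70.0)):
            center = np.array([cx, 100.0])
            half = np.radians(opening / 2)
            d1 = np.array([np.sin(half), -np.cos(half)])
            d2 = np.array([-np.sin(half), -np.cos(half)])
            c = g.add_node([tuple(np.round(center).astype(int))])
            for d in (d1, d2, np.array([0.0, 1.0])):
                tip = center + 60 * d
                t = g.add_node([tuple(np.round(tip).astype(int))])
                g.add_edge(_path(center, tip), c, t)
        assert vessel_angle_mean(g, od) == pytest.approx(60.0, abs=2.0)

    def test_no_bifurcations_gives_missing(self):
        g, _ = _star_graph((50.0, 50.0), [(50.0, 10.0), (90.0, 50.0)])
        assert vessel_angle_mean(g, (0.0, 0.0)) is None


class TestVesselDensity:
    def test_arithmetic(self):
        from vesselmorph.roi import RoiRing
        ring = RoiRing((0.0, 0.0), 10.0, 20.0, pixel_count=10_000)
        mask = np.zeros((200, 200), bool)
        mask[:50, :5] = True  # 250 px
        assert vessel_density(mask, ring, "roi_area") == pytest.approx(2.5)

    def test_empty_mask_zero(self):
        from vesselmorph.roi import RoiRing
        ring = RoiRing((0.0, 0.0), 10.0, 20.0, pixel_count=100)
        assert vessel_density(np.zeros((10, 10), bool), ring) == 0.0

    def test_full_ring_is_100_percent(self):
        roi = build_roi(Circle((50.0, 50.0), 10.0), 100, 100)
        full = mask_to_roi(np.ones((100, 100), bool), roi)
        assert vessel_density(full, roi, "roi_area") == pytest.approx(100.0)

    def test_image_area_denominator(self):
        from vesselmorph.roi import RoiRing
        ring = RoiRing((0.0, 0.0), 10.0, 20.0, pixel_count=1)
        mask = np.zeros((100, 100), bool)
        mask[0, :50] = True
        assert vessel_density(mask, ring, "image_area") == pytest.approx(0.5)

    def test_density_invariant_under_90_degree_rotation(self):
        p = SynthParams(seed=8, image_width=1200, image_height=1200,
                        od_center=(600.0, 600.0))
        vessel, od, _ = generate_tree(p)
        def density(v, o):
            roi = build_roi(mec_of_mask(o), o.shape[1], o.shape[0])
            return vessel_density(mask_to_roi(v, roi), roi)
        d0 = density(vessel, od)
        d90 = density(np.rot90(vessel).copy(), np.rot90(od).copy())
        assert d90 == pytest.approx(d0, rel=0.01)


class TestFractalDimension:
    def test_straight_line_dimension_one(self):
        mask = np.zeros((8, 512), bool)
        mask[3, :] = True
        fd = fractal_dimension(mask, box_sizes=[2, 4, 8, 16, 32, 64, 128])
        assert 0.95 <= fd <= 1.05

    def test_filled_block_dimension_two(self):
        mask = np.ones((512, 512), bool)
        fd = fractal_dimension(mask, box_sizes=[2, 4, 8, 16, 32, 64, 128])
        assert 1.90 <= fd <= 2.0

    def test_sierpinski_triangle(self):
        # bitwise construction of the Sierpinski right triangle
        expected = np.log(3) / np.log(2)
        fds = {}
        for size in (512, 1024):
            xs, ys = np.meshgrid(np.arange(size), np.arange(size))
            mask = (xs & ys) == 0
            fds[size] = fractal_dimension(mask, box_sizes=[2, 4, 8, 16, 32, 64, 128])
        assert fds[512] == pytest.approx(expected, abs=0.05)
        # convergence: the finer construction agrees at least as well
        assert abs(fds[1024] - expected) <= abs(fds[512] - expected) + 0.01

    def test_translation_by_whole_boxes_invariant(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((300, 300), bool)
        mask[50:200, 50:200] = rng.random((150, 150)) < 0.2
        sizes = [2, 4, 8, 16]
        a = fractal_dimension(mask, sizes, anchor=(0, 0))
        shifted = np.roll(np.roll(mask, 16, axis=0), 32, axis=1)
        b = fractal_dimension(shifted, sizes, anchor=(0, 0))
        assert b == pytest.approx(a, abs=1e-9)

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            fractal_dimension(np.ones((10, 10), bool), box_sizes=[4])

    def test_default_box_sizes_dyadic(self):
        assert default_box_sizes(512) == [2, 4, 8, 16, 32, 64, 128]


def semicircle(radius, center=(200.0, 200.0), n=4000):
    th = np.linspace(0.0, np.pi, n)
    return np.column_stack([radius * np.cos(th) + center[0],
                            radius * np.sin(th) + center[1]])


class TestSegmentTortuosity:
    def test_straight_segment_is_zero(self):
        path = np.column_stack([np.arange(200.0), np.zeros(200)])
        assert segment_tortuosity(path) <= 1e-6
        diag = np.column_stack([np.arange(200.0), np.arange(200.0)])
        assert segment_tortuosity(diag) <= 1e-6

    @pytest.mark.parametrize("radius", [25, 50, 100])
    def test_semicircle_constant_curvature(self, radius, pixel_chain):
        tau = segment_tortuosity(pixel_chain(semicircle(radius)))
        assert tau == pytest.approx(1.0 / radius ** 2, rel=0.05)

    def test_inverse_square_scale_law(self):
        # scaling a path by s scales tau by 1/s^2 (semicircle family)
        taus = {s: segment_tortuosity(semicircle(40 * s, center=(300, 300)))
                for s in (1.0, 2.0, 3.0)}
        for s in (2.0, 3.0):
            assert taus[s] * s ** 2 == pytest.approx(taus[1.0], rel=0.06)

    def test_generator_sinusoids_match_quadrature_oracle(self, pixel_chain):
        # mean over the rasterized centerlines of one default tree
        _, _, truth = generate_tree(SynthParams(seed=21))
        ratios = []
        for seg in truth.segments:
            est = segment_tortuosity(pixel_chain(seg.polyline))
            oracle = analytic_tortuosity_of_sinusoid(
                seg.amplitude, seg.wavelength_eff, seg.chord_length)
            ratios.append(est / oracle)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)

    def test_too_short_path_rejected(self):
        with pytest.raises(ValueError, match="short"):
            segment_tortuosity(np.column_stack([np.arange(8.0), np.zeros(8)]))


class TestEyeTortuosity:
    def _graph_with_paths(self, paths):
        g = VesselGraph()
        for path in paths:
            a = g.add_node([tuple(np.round(path[0]).astype(int))])
            b = g.add_node([tuple(np.round(path[-1]).astype(int))])
            g.add_edge(path, a, b)
        return g

    def test_single_segment_identity(self):
        path = semicircle(50)
        g = self._graph_with_paths([path])
        assert eye_tortuosity(g) == pytest.approx(1e3 * segment_tortuosity(path))

    def test_length_weighted_mean(self):
        p1, p2 = semicircle(50), semicircle(25, center=(500, 500))
        g = self._graph_with_paths([p1, p2])
        l1, l2 = np.pi * 50, np.pi * 25
        expected = 1e3 * ((segment_tortuosity(p1) * l1 + segment_tortuosity(p2) * l2)
                          / (l1 + l2))
        assert eye_tortuosity(g) == pytest.approx(expected, rel=0.02)

    def test_short_segments_excluded(self):
        short = np.column_stack([np.arange(12.0), np.zeros(12)])
        g = self._graph_with_paths([short])
        assert eye_tortuosity(g, min_seg_len=30) is None


class TestAnalyzeEye:
    def test_empty_vessel_mask_yields_missing_metrics(self):
        od = np.zeros((600, 800), bool)
        ys, xs = np.ogrid[0:600, 0:800]
        od |= (xs - 400) ** 2 + (ys - 300) ** 2 <= 30 ** 2
        frame = FundusFrame("e", "g", np.zeros((600, 800), bool), od)
        roi = build_roi(mec_of_mask(od), 800, 600)
        rec = analyze_eye(frame, roi)
        assert rec.vessel_density == 0.0
        assert rec.vessel_angle_mean is None
        assert rec.fractal_dimension is None
        assert rec.tortuosity is None
        assert "empty vessel mask" in rec.notes

    def test_bit_identical_across_runs(self):
        vessel, od, _ = generate_tree(SynthParams(seed=33))
        frame = FundusFrame("e", "g", vessel, od)
        roi = build_roi(mec_of_mask(od), frame.width, frame.height)
        r1 = analyze_eye(frame, roi)
        r2 = analyze_eye(frame, roi)
        assert vars(r1) == vars(r2)

    def test_metric_ranges(self):
        vessel, od, _ = generate_tree(SynthParams(seed=34))
        frame = FundusFrame("e", "g", vessel, od)
        roi = build_roi(mec_of_mask(od), frame.width, frame.height)
        rec = analyze_eye(frame, roi)
        assert 0 <= rec.vessel_density <= 100
        assert 0 <= rec.fractal_dimension <= 2
        assert rec.tortuosity >= 0
        assert 0 < rec.vessel_angle_mean < 180
        assert rec.n_bifurcations > 0
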