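"""Leaf and stem trait measurement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import phenocloud as pc
from phenocloud.errors import MeasurementError
from phenocloud.segmentation import SegmentedPlant
from phenocloud.synthetic import _arc_points, _leaf_frame
from phenocloud.traits import WidthResult

Z = np.array([0.0, 0.0, 1.0])


def _segment_line(start, stop, n):
    return np.linspace(start, stop, n)


class TestApexStipule:
    def test_collinear_extremes(self):
        leaf = _segment_line([0, 0, 5], [4, 0, 5], 9)
        stem = _segment_line([0, 0, 0], [0, 0, 10], 20)
        apex, stipule = pc.find_apex_stipule(leaf, stem)
        assert np.allclose(stipule, [0, 0, 5])
        assert np.allclose(apex, [4, 0, 5])

    @pytest.mark.parametrize("n", [20, 300])
    def test_matches_brute_force_diameter(self, rng, n):
        leaf = rng.normal(0, 1, (n, 3))
        stem = rng.normal(5, 0.1, (30, 3))
        apex, stipule = pc.find_apex_stipule(leaf, stem)
        d = np.linalg.norm(leaf[:, None] - leaf[None], axis=-1)
        assert np.linalg.norm(apex - stipule) == pytest.approx(d.max(), abs=1e-12)

    def test_large_leaf_uses_hull_but_stays_exact(self, rng):
        leaf = rng.normal(0, 1, (1000, 3))
        stem = rng.normal(5, 0.1, (30, 3))
        apex, stipule = pc.find_apex_stipule(leaf, stem)
        d = np.linalg.norm(leaf[:, None] - leaf[None], axis=-1)
        assert np.linalg.norm(apex - stipule) == pytest.approx(d.max(), abs=1e-12)

    def test_degenerate_leaf_rejected(self):
        with pytest.raises(MeasurementError):
            pc.find_apex_stipule(np.zeros((4, 3)), np.zeros((10, 3)))


class TestMidribPolyline:
    def test_straight_leaf_gives_collinear_equispaced_points(self, rng):
        t = rng.uniform(0, 1, 400)
        leaf = np.outer(t, [4.0, 0, 0])
        poly = pc.midrib_polyline(leaf, np.array([4.0, 0, 0]), np.zeros(3))
        assert poly.shape == (7, 3)
        # all on the chord, boundaries at 1/6 steps (slab centroids wobble
        # by at most half a slab width around each boundary)
        assert np.allclose(poly[:, 1:], 0)
        expected = np.linspace(0, 4, 7)
        assert np.allclose(poly[:, 0], expected, atol=4 / 6 / 4)

    def test_zero_internal_points_is_chord(self, rng):
        leaf = rng.normal(0, 1, (50, 3))
        poly = pc.midrib_polyline(leaf, np.array([1.0, 0, 0]), np.zeros(3),
                                  n_internal=0)
        assert np.allclose(poly, [[0, 0, 0], [1, 0, 0]])

    def test_semicircular_leaf_tracks_true_midrib(self):
        spec = pc.LeafSpec(midrib_arc_length=4.0, curl_angle_deg=180.0,
                           inclination_deg=30.0)
        rng = np.random.default_rng(7)
        points, truth = pc.synthetic.generate_leaf(
            spec, np.zeros(3), azimuth_deg=0.0, rng=rng,
            points_per_cm2=200.0, noise_sigma=0.0)
        poly = pc.midrib_polyline(points, truth["apex"], truth["stipule"])
        e1, e2, _ = _leaf_frame(0.0, 30.0)
        true_midrib = _arc_points(np.linspace(0, 1, 2000), 4.0, np.pi,
                                  np.zeros(3), e1, e2)
        for p in poly[1:-1]:
            dist = np.linalg.norm(true_midrib - p, axis=1).min()
            assert dist <= spec.width / 2

    def test_coincident_endpoints_rejected(self, rng):
        leaf = rng.normal(0, 1, (20, 3))
        with pytest.raises(MeasurementError):
            pc.midrib_polyline(leaf, np.zeros(3), np.zeros(3))


class TestLeafLength:
    def test_collinear_unit_spacing(self):
        poly = np.outer(np.arange(7), [1.0, 0, 0])
        assert pc.leaf_length(poly) == pytest.approx(6.0)

    def test_semicircle_closed_form(self):
        poly = pc.arc_polyline(np.pi, 180.0, n_internal=5)
        assert pc.leaf_length(poly) == pytest.approx(12 * np.sin(np.pi / 12),
                                                     abs=1e-9)

    def test_straight_polyline_equals_chord(self, rng):
        a, s = rng.normal(0, 3, 3), rng.normal(0, 3, 3)
        poly = np.linspace(s, a, 7)
        assert pc.leaf_length(poly) == pytest.approx(np.linalg.norm(a - s))

    def test_dominates_chord(self, rng):
        for _ in range(50):
            poly = rng.normal(0, 1, (7, 3))
            chord = np.linalg.norm(poly[-1] - poly[0])
            assert pc.leaf_length(poly) >= chord - 1e-12

    def test_too_short_polyline(self):
        with pytest.raises(MeasurementError):
            pc.leaf_length(np.zeros((1, 3)))


class TestLeafWidth:
    def test_rectangular_strip(self):
        x, y = np.meshgrid(np.linspace(0, 4, 120), np.linspace(-0.5, 0.5, 40))
        leaf = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
        res = pc.leaf_width(leaf, np.array([4.0, 0, 0]), np.zeros(3))
        assert res.width == pytest.approx(1.0, rel=1e-6)

    def test_flat_ellipse_recovers_minor_axis(self):
        x, y = np.meshgrid(np.linspace(-3, 3, 300), np.linspace(-1, 1, 160))
        inside = (x / 3) ** 2 + y ** 2 <= 1
        leaf = np.column_stack([x[inside], y[inside], np.zeros(inside.sum())])
        res = pc.leaf_width(leaf, np.array([3.0, 0, 0]), np.array([-3.0, 0, 0]))
        assert res.width == pytest.approx(2.0, rel=0.02)
        # the endpoints really are leaf points
        assert np.linalg.norm(leaf - res.left, axis=1).min() == 0
        assert np.linalg.norm(leaf - res.right, axis=1).min() == 0

    def test_matches_per_band_brute_force(self, rng):
        leaf = rng.normal(0, 1, (400, 3)) * [3.0, 1.0, 0.2]
        apex, stipule = np.array([3.5, 0, 0]), np.array([-3.5, 0, 0])
        res = pc.leaf_width(leaf, apex, stipule, n_bands=25)
        # independent frame + scan
        e1 = (apex - stipule) / np.linalg.norm(apex - stipule)
        centered = leaf - leaf.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        e2 = vt[1] - (vt[1] @ e1) * e1
        e2 /= np.linalg.norm(e2)
        t = (leaf - stipule) @ e1
        edges = np.linspace(t.min(), t.max(), 26)
        best = 0.0
        for b in range(25):
            hi = t <= edges[b + 1] if b == 24 else t < edges[b + 1]
            sel = leaf[(t >= edges[b]) & hi]
            if len(sel) == 0:
                continue
            s = sel @ e2
            w = np.linalg.norm(sel[np.argmin(s)] - sel[np.argmax(s)])
            best = max(best, w)
        assert res.width == pytest.approx(best, rel=1e-9)

    def test_collinear_leaf_degenerates_to_zero(self):
        leaf = _segment_line([0, 0, 0], [5, 0, 0], 50)
        res = pc.leaf_width(leaf, np.array([5.0, 0, 0]), np.zeros(3))
        assert res.width == 0.0 and res.degenerate


class TestStemHeight:
    def test_straight_vertical_stem(self):
        stem = _segment_line([0, 0, 0], [0, 0, 20], 201)
        height, marks = pc.stem_height(stem, top_attachment=[0.1, 0, 20])
        assert height == pytest.approx(20.0, abs=1e-9)
        assert np.allclose(marks[0], [0, 0, 0])
        assert np.allclose(marks[2], [0, 0, 20])

    def test_bent_stem_two_chord_closed_form(self):
        # 60 degree bend, arc length 20: chords subtend 30 degrees each
        stem = _arc_points(np.linspace(0, 1, 2001), 20.0, np.radians(60.0),
                           np.zeros(3), Z, np.array([1.0, 0, 0]))
        height, _ = pc.stem_height(stem)
        expected = 20.0 * np.sin(np.radians(15)) / (np.pi / 12)
        assert height == pytest.approx(expected, abs=1e-6)

    def test_collinear_marks_reduce_to_chord(self):
        stem = _segment_line([0, 0, 0], [0, 0, 10], 101)
        height, marks = pc.stem_height(stem)
        assert height == pytest.approx(
            np.linalg.norm(marks[2] - marks[0]), abs=1e-12)

    def test_tiny_stem_rejected(self):
        with pytest.raises(MeasurementError):
            pc.stem_height(np.zeros((3, 3)))


class TestMeasurePlant:
    def test_recovers_gentle_synthetic_plant_within_2pct(self, small_plant):
        cloud, truth = small_plant
        plant, _ = pc.segment_plant(cloud)
        traits = pc.measure_plant(plant)
        assert traits.n_leaves == truth.n_leaves
        assert traits.stem_height == pytest.approx(truth.stem_height, rel=0.02)
        for j, leaf in enumerate(traits.leaves):
            assert leaf.length == pytest.approx(truth.leaf_lengths[j], rel=0.02)

    def test_deterministic(self, small_plant):
        cloud, _ = small_plant
        plant, _ = pc.segment_plant(cloud)
        a = pc.measure_plant(plant).to_dict()
        b = pc.measure_plant(plant).to_dict()
        assert a == b

    def test_tiny_leaf_skipped_with_warning(self, small_plant):
        cloud, _ = small_plant
        plant, _ = pc.segment_plant(cloud)
        # graft a 3-point pseudo-leaf cluster
        from phenocloud.segmentation import Cluster
        fake = Cluster(np.array([0, 1, 2]))
        crippled = SegmentedPlant(plant.stem, plant.leaves + [fake],
                                  plant.residual_indices, plant.cloud)
        traits = pc.measure_plant(crippled)
        assert len(traits.leaves) == len(plant.leaves)
        assert any("skipped" in w for w in traits.warnings)

    def test_rigid_motion_invariance(self, small_plant):
        cloud, _ = small_plant
        plant, _ = pc.segment_plant(cloud)
        base = pc.measure_plant(plant)
        rot = Rotation.from_euler("xyz", [35, -20, 120], degrees=True).as_matrix()
        moved = cloud.transformed(rotation=rot, translation=[5, -3, 2])
        moved_plant = SegmentedPlant(plant.stem, plant.leaves,
                                     plant.residual_indices, moved)
        other = pc.measure_plant(moved_plant, up=rot @ Z)
        assert other.stem_height == pytest.approx(base.stem_height, rel=1e-9)
        for a, b in zip(base.leaves, other.leaves):
            assert b.length == pytest.approx(a.length, rel=1e-9)
            assert b.width == pytest.approx(a.width, rel=1e-9)

    def test_uniform_scaling_scales_all_lengths(self, small_plant):
        cloud, _ = small_plant
        plant, _ = pc.segment_plant(cloud)
        base = pc.measure_plant(plant)
        scaled_plant = SegmentedPlant(plant.stem, plant.leaves,
                                      plant.residual_indices,
                                      cloud.transformed(scale=2.5))
        other = pc.measure_plant(scaled_plant)
        assert other.stem_height == pytest.approx(2.5 * base.stem_height,
                                                  rel=1e-9)
        for a, b in zip(base.leaves, other.leaves):
            assert b.length == pytest.approx(2.5 * a.length, rel=1e-9)

    def test_manual_stem_points_override(self, small_plant):
        cloud, _ = small_plant
        plant, _ = pc.segment_plant(cloud)
        marks = np.array([[0, 0, 0], [0, 0, 6], [0, 0, 12.0]])
        traits = pc.measure_plant(plant, stem_points_manual=marks)
        assert traits.stem_height == pytest.approx(12.0)

    def test_count_leaves(self, small_plant):
        cloud, truth = small_plant
        plant, _ = pc.segment_plant(cloud)
        assert pc.count_leaves(plant) == truth.n_leaves
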