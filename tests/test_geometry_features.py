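"""Geometric predictors: APD, undulation index, centerline curvature."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from aaamorph.geometry_features import (Centerline, GeometricFeatures,
                                        circumradius, convex_hull_volume,
                                        extract_all_features,
                                        extract_centerline, max_ap_diameter,
                                        min_radius_of_curvature,
                                        undulation_index, _circumradii)
from aaamorph.synthetic_cohort import (LobulationSpec, PhantomSpec,
                                       generate_dumbbell, generate_phantom,
                                       make_cuboid, make_sphere)
from aaamorph.volume_io import VoxelVolume

finite = st.floats(-50, 50, allow_nan=False, allow_infinity=False)
point = st.tuples(finite, finite, finite)


class TestCircumradius:
    def test_collinear_is_infinite(self):
        assert math.isinf(circumradius((0, 0, 0), (1, 0, 0), (2, 0, 0)))
        assert math.isinf(circumradius((0, 0, 0), (0, 0, 0), (1, 2, 3)))

    def test_symmetric_triangle(self):
        # circle through (0,0), (1,1), (2,0) is centered at (1,0), radius 1
        assert circumradius((0, 0, 0), (1, 1, 0), (2, 0, 0)) == pytest.approx(1.0)

    def test_equilateral_closed_form(self):
        # side a -> R = a / sqrt(3)
        p1, p2, p3 = (0, 0, 0), (2, 0, 0), (1, math.sqrt(3), 0)
        assert circumradius(p1, p2, p3) == pytest.approx(2 / math.sqrt(3))

    @settings(max_examples=60, derandomize=True)
    @given(p1=point, p2=point, p3=point,
           angles=st.tuples(finite, finite, finite), shift=point,
           scale=st.floats(0.1, 10))
    def test_rigid_motion_invariance_and_scaling(self, p1, p2, p3, angles, shift, scale):
        r0 = circumradius(p1, p2, p3)
        rot = Rotation.from_euler("xyz", angles, degrees=True)
        pts = rot.apply(np.array([p1, p2, p3])) + np.asarray(shift)
        r1 = circumradius(*pts)
        if math.isinf(r0) or math.isinf(r1):
            # near-degenerate triangles can cross the collinearity tolerance
            # under rotation round-off; both readings must then be huge
            assert min(r0, r1) > 1e3 or math.isinf(min(r0, r1))
            return
        assert r1 == pytest.approx(r0, rel=1e-6)
        r2 = circumradius(*(np.array([p1, p2, p3]) * scale))
        assert r2 == pytest.approx(r0 * scale, rel=1e-6)


class TestMinRadiusOfCurvature:
    def test_straight_line_sentinel(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)])
        rc, idx = min_radius_of_curvature(pts)
        assert math.isinf(rc) and idx is None

    def test_circle_samples_recover_radius(self):
        theta = np.linspace(0, 2 * math.pi, 30, endpoint=False)
        pts = np.column_stack([35 * np.cos(theta), 35 * np.sin(theta), np.zeros(30)])
        rc, idx = min_radius_of_curvature(pts)
        assert rc == pytest.approx(35.0, abs=0.5)
        assert idx is not None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_polylines(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3)) * 20
        rc, idx = min_radius_of_curvature(pts)
        brute = min(circumradius(pts[i - 1], pts[i], pts[i + 1])
                    for i in range(1, 9))
        assert rc == pytest.approx(brute, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            min_radius_of_curvature(np.zeros((2, 3)) + [[0, 0, 0], [1, 1, 1]])

    def test_end_exclusion_skips_terminal_triplets(self):
        # a sharp kink at the first interior point, straight afterwards
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0]] +
                       [[3 + i, -1 - i, 0] for i in range(17)], float)
        rc_all, _ = min_radius_of_curvature(pts)
        rc_core, _ = min_radius_of_curvature(pts, exclude_end_fraction=0.2)
        assert rc_all < rc_core


class TestAPD:
    def test_cuboid_extent(self):
        assert max_ap_diameter(make_cuboid((20, 30, 10))) == 30.0

    def test_anisotropic_ap_spacing(self):
        v = make_cuboid((20, 30, 10), spacing=(1.0, 0.7, 1.0))
        assert max_ap_diameter(v) == pytest.approx(21.0)

    def test_sphere_diameter_within_one_voxel(self):
        assert max_ap_diameter(make_sphere(25.0)) == pytest.approx(50.0, abs=1.0)

    def test_pairwise_mode_at_least_extent(self):
        v = make_cuboid((6, 30, 10))
        ext = max_ap_diameter(v, mode="extent")
        pw = max_ap_diameter(v, mode="pairwise")
        # in-slice diagonal of a 30 x 10 voxel slab (center-to-center)
        assert pw == pytest.approx(math.hypot(29, 9))
        assert pw >= ext - 1.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            max_ap_diameter(make_cuboid(), mode="volumetric")


class TestConvexHullVolume:
    def test_cuboid_exact(self):
        assert convex_hull_volume(make_cuboid((20, 30, 10))) == pytest.approx(6000.0)

    def test_anisotropic_cuboid(self):
        v = make_cuboid((20, 30, 10), spacing=(1.0, 0.5, 2.0))
        assert convex_hull_volume(v) == pytest.approx(6000.0)

    def test_l_shape_matches_shoelace_oracle(self):
        # two abutting cuboids forming an L in the (axial, AP) plane
        mask = np.zeros((24, 34, 12), bool)
        mask[2:22, 2:12, 1:11] = True    # 20 x 10 arm
        mask[2:12, 12:32, 1:11] = True   # 10 x 20 arm
        v = VoxelVolume(mask, (1, 1, 1))
        # hull cross-section polygon (voxel corners), area by the shoelace formula
        poly = np.array([[1.5, 1.5], [21.5, 1.5], [21.5, 11.5],
                         [11.5, 31.5], [1.5, 31.5]])
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert convex_hull_volume(v) == pytest.approx(area * 10.0, rel=1e-12)


class TestUndulationIndex:
    def test_convex_cuboid_is_exactly_zero(self):
        assert undulation_index(make_cuboid((20, 30, 10))) == 0.0

    def test_sphere_ui_small_and_shrinks_with_spacing(self):
        # the staircase concavity of a voxelized ball is a real concavity of
        # the voxel solid; it scales with the voxel size
        coarse = undulation_index(make_sphere(25.0, spacing=1.0))
        fine = undulation_index(make_sphere(25.0, spacing=0.5))
        assert 0.0 < coarse < 0.08
        assert fine < coarse

    def test_dumbbell_matches_solid_geometry_oracle(self):
        v, truth = generate_dumbbell(radius=20.0, separation=80.0,
                                     neck_radius=5.0, spacing=1.0)
        assert undulation_index(v) == pytest.approx(truth.ui, abs=0.05)

    def test_bounded_on_arbitrary_masks(self, rng):
        mask = rng.random((12, 12, 12)) > 0.6
        mask[5, 5, 5] = True
        ui = undulation_index(VoxelVolume(mask, (1, 1, 1)))
        assert 0.0 <= ui < 1.0

    def test_axis_permutation_invariance(self):
        v, _ = generate_dumbbell(radius=12.0, separation=50.0, neck_radius=4.0)
        ui0 = undulation_index(v)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            vp = VoxelVolume(np.transpose(v.mask, perm),
                             tuple(np.asarray(v.spacing)[list(perm)]))
            assert undulation_index(vp) == pytest.approx(ui0, rel=1e-12)

    def test_uniform_scaling_invariance(self):
        v = make_cuboid((8, 12, 6))
        base = undulation_index(v)
        scaled = undulation_index(VoxelVolume(v.mask, (2.0, 2.0, 2.0)))
        assert scaled == pytest.approx(base, abs=1e-12)


class TestCenterline:
    def test_straight_cylinder_on_axis(self):
        vol, truth = generate_phantom(PhantomSpec(base_radius_mm=15.0, length_mm=60.0))
        cl = extract_centerline(vol)
        # every point within 1 mm of the true axis (constant y, x)
        dev = np.abs(cl.points[:, 1:] - truth.axis_mm[0, 1:]).max()
        assert dev <= 1.0
        assert len(cl) == vol.n_axial_slices

    def test_bent_tube_tracks_arc(self):
        spec = PhantomSpec(base_radius_mm=10.0, length_mm=80.0, bend_radius_mm=40.0)
        vol, truth = generate_phantom(spec)
        cl = extract_centerline(vol)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(truth.axis_mm).query(cl.points)
        assert d.max() <= 1.5

    def test_two_slice_mask_rejected(self):
        mask = np.zeros((2, 10, 10), bool)
        mask[:, 2:8, 2:8] = True
        with pytest.raises(ValueError, match="axial slices"):
            extract_centerline(VoxelVolume(mask, (1, 1, 1)))

    def test_centerline_type_invariants(self):
        with pytest.raises(ValueError):
            Centerline(np.zeros((2, 3)), 5)
        with pytest.raises(ValueError):
            Centerline(np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1]], float), 3)


class TestExtractAllFeatures:
    def test_straight_cylinder_composite(self):
        vol, _ = generate_phantom(PhantomSpec(base_radius_mm=15.0, length_mm=60.0))
        f = extract_all_features(vol)
        assert f.apd == pytest.approx(30.0, abs=1.0)
        assert f.ui < 0.08
        assert math.isinf(f.min_rc)
        assert f.min_rc_capped == 10_000.0

    def test_matches_individual_calls(self):
        spec = PhantomSpec(base_radius_mm=12.0, length_mm=70.0, bend_radius_mm=50.0,
                           lobulation=LobulationSpec(amplitude_mm=3.0, n_lobes=3))
        vol, _ = generate_phantom(spec)
        f = extract_all_features(vol)
        assert f.apd == max_ap_diameter(vol)
        assert f.ui == undulation_index(vol)
        cl = extract_centerline(vol)
        rc, _ = min_radius_of_curvature(cl, stride=max(1, len(cl) // 5),
                                        exclude_end_fraction=0.1)
        assert f.min_rc == rc

    def test_deterministic(self):
        vol, _ = generate_phantom(PhantomSpec(base_radius_mm=12.0, length_mm=60.0,
                                              bend_radius_mm=45.0))
        f1 = extract_all_features(vol)
        f2 = extract_all_features(vol)
        assert (f1.apd, f1.ui, f1.min_rc) == (f2.apd, f2.ui, f2.min_rc)


class TestGeometricFeaturesType:
    @pytest.mark.parametrize("kwargs", [
        dict(apd=0.0, ui=0.1, min_rc=30.0),
        dict(apd=50.0, ui=1.0, min_rc=30.0),
        dict(apd=50.0, ui=-0.1, min_rc=30.0),
        dict(apd=50.0, ui=0.1, min_rc=0.0),
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            GeometricFeatures(**kwargs)

    def test_infinite_rc_allowed(self):
        f = GeometricFeatures(apd=50.0, ui=0.1, min_rc=math.inf)
        assert f.min_rc_capped == 10_000.0
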