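"""Excess-tissue tumor segmentation and shape analytics."""

import numpy as np
import pytest

from mousecbct.anatomy import build_symmetry_chain, segment_bone, segment_teeth
from mousecbct.phantom import TumorSpec, make_mouse_phantom
from mousecbct.pipeline import SegmentationConfig, segment_mouse
from mousecbct.symmetry import build_grid, refine_grid, resample_head
from mousecbct.tumorseg import (
    HeightMap,
    TumorSegmentation,
    backproject_tumor,
    ellipsoid_volume,
    excess_height_map,
    filter_height_map,
    shape_eigen,
    sphericalness,
    tumor_location,
)


def stages(vol, refine=True):
    teeth = segment_teeth(vol)
    chain = build_symmetry_chain(segment_bone(vol, teeth), teeth)
    grid = build_grid(chain, vol.spacing_mm)
    if refine:
        grid = refine_grid(grid, vol, max_steps=10)
    head = resample_head(vol, grid)
    return teeth, grid, head


def ellipsoid_mask(semi_mm, spacing, angle_deg=0.0):
    """Voxelized solid ellipsoid, optionally rotated about z."""
    pad = max(semi_mm) + 2 * spacing
    n = int(np.ceil(2 * pad / spacing))
    ax = (np.arange(n) + 0.5) * spacing - pad
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    th = np.deg2rad(angle_deg)
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y
    inside = (xr / semi_mm[0]) ** 2 + (yr / semi_mm[1]) ** 2 + (z / semi_mm[2]) ** 2 <= 1
    return TumorSegmentation(inside, inside.sum() * spacing**3, "right", spacing, np.zeros(3))


class TestExcessHeightMap:
    def test_symmetric_head_has_near_zero_mean(self):
        vol, _ = make_mouse_phantom(seed=3)
        _, _, head = stages(vol, refine=False)
        hm = excess_height_map(head, "right")
        # per-column noise floor: a fraction of one voxel volume
        assert abs(hm.values.mean()) < vol.spacing_mm**3

    def test_right_tumor_mass_recovered_in_map(self, tumor_phantom_50):
        vol, truth = tumor_phantom_50
        _, _, head = stages(vol, refine=False)
        hm = excess_height_map(head, "right")
        truth_v = truth.mice[0].tumor_volume_mm3
        assert abs(hm.total_mm3() - truth_v) < 0.10 * truth_v

    def test_left_tumor_appears_negative_when_looking_right(self):
        vol, truth = make_mouse_phantom(
            seed=6, tumor=TumorSpec.from_volume(50.0, side="left")
        )
        _, _, head = stages(vol, refine=False)
        hm = excess_height_map(head, "right")
        truth_v = truth.mice[0].tumor_volume_mm3
        assert hm.total_mm3() < -0.8 * truth_v
        hm_left = excess_height_map(head, "left")
        assert abs(hm_left.total_mm3() - truth_v) < 0.10 * truth_v


class TestFilterHeightMap:
    def test_subthreshold_noise_zeroed(self):
        rng = np.random.default_rng(0)
        s = 0.4
        hm = HeightMap(rng.normal(0, 0.01 * s**2, (30, 20)), "right", s)
        filtered = filter_height_map(hm, min_thickness_mm=0.4)
        assert not filtered.values.any()

    def test_largest_region_survives(self):
        s = 0.4
        v = np.zeros((40, 30))
        v[5:8, 5:8] = 1.0  # small blob
        v[20:35, 5:25] = 1.0  # 10x larger blob
        filtered = filter_height_map(HeightMap(v, "right", s), min_thickness_mm=0.4)
        assert not filtered.values[5:8, 5:8].any()
        assert filtered.values[22:33, 8:22].any()

    def test_negative_values_clamped(self):
        s = 0.4
        v = np.full((20, 20), -1.0)
        filtered = filter_height_map(HeightMap(v, "right", s))
        assert np.all(filtered.values == 0.0)


class TestBackprojectTumor:
    def test_empty_map_gives_empty_segmentation(self, symmetric_phantom):
        vol, _ = symmetric_phantom
        _, grid, head = stages(vol, refine=False)
        hm = filter_height_map(excess_height_map(head, "right"))
        seg = backproject_tumor(hm, grid, head, vol)
        assert seg.volume_mm3 <= 2.0

    def test_tumor_volume_and_overlap(self, tumor_result_50, tumor_phantom_50):
        res, truth = tumor_result_50
        mt = truth.mice[0]
        assert abs(res.volume_mm3 - mt.tumor_volume_mm3) < 0.10 * mt.tumor_volume_mm3
        seg = res.segmentation
        inter = (seg.mask & mt.tumor_mask).sum()
        dice = 2 * inter / (seg.mask.sum() + mt.tumor_mask.sum())
        assert dice >= 0.7

    def test_pose_jitter_repeatability(self):
        vols = []
        for seed, bend in ((10, 4.0), (11, -5.0)):
            vol, _ = make_mouse_phantom(
                seed=seed, bend_deg=bend, tumor=TumorSpec.from_volume(80.0)
            )
            res = segment_mouse(vol)
            vols.append(res.volume_mm3)
        assert abs(vols[1] - vols[0]) / vols[0] < 0.10


class TestShapeEigen:
    def test_uniform_ellipsoid_moments(self):
        seg = ellipsoid_mask((4.0, 2.0, 2.0), spacing=0.1)
        m = shape_eigen(seg)
        assert m.eigenvalues_mm2[0] == pytest.approx(16.0 / 5.0, rel=0.02)
        assert m.eigenvalues_mm2[1] == pytest.approx(4.0 / 5.0, rel=0.02)
        assert m.normalized == pytest.approx([0.5, 0.25, 0.25], rel=0.02)

    def test_sphere_has_equal_normalized_eigenvalues(self):
        seg = ellipsoid_mask((2.5, 2.5, 2.5), spacing=0.1)
        m = shape_eigen(seg)
        assert m.normalized == pytest.approx([1 / 3] * 3, rel=0.01)

    def test_rotation_invariance(self):
        a = shape_eigen(ellipsoid_mask((4.0, 2.0, 2.0), 0.1))
        b = shape_eigen(ellipsoid_mask((4.0, 2.0, 2.0), 0.1, angle_deg=30.0))
        assert np.allclose(a.eigenvalues_mm2, b.eigenvalues_mm2, rtol=0.01)

    def test_degenerate_mask_rejected(self):
        flat = np.zeros((5, 5, 5), dtype=bool)
        flat[:, :, 2] = True
        seg = TumorSegmentation(flat, flat.sum() * 0.064, "right", 0.4, np.zeros(3))
        with pytest.raises(ValueError):
            shape_eigen(seg)


class TestEllipsoidVolume:
    def test_sphere_volume_exact_relation(self):
        r = 3.0
        from mousecbct.tumorseg import ShapeMetrics

        lam = np.array([r**2 / 5] * 3)
        m = ShapeMetrics(lam, np.full(3, 1 / 3), np.eye(3), np.zeros(3))
        assert ellipsoid_volume(m) == pytest.approx(4 / 3 * np.pi * r**3, rel=1e-12)

    def test_voxelized_ellipsoid_consistency(self):
        seg = ellipsoid_mask((4.0, 2.0, 2.0), spacing=0.1)
        m = shape_eigen(seg)
        expected = 4 / 3 * np.pi * 16.0
        assert ellipsoid_volume(m) == pytest.approx(expected, rel=0.02)
        assert ellipsoid_volume(m) == pytest.approx(seg.volume_mm3, rel=0.05)


def brute_force_sphericalness(seg, grid_step=0.25):
    """Oracle: dense center search over a wide window (voxel units)."""
    idx = np.argwhere(seg.mask)
    coords = (idx + 0.5) * seg.spacing_mm
    volume = len(coords) * seg.spacing_mm**3
    r = (3 * volume / (4 * np.pi)) ** (1 / 3)
    centroid = coords.mean(axis=0)
    best = 0.0
    offs = np.arange(-2.0, 2.01, grid_step) * seg.spacing_mm
    for dx in offs:
        for dy in offs:
            for dz in offs:
                c = centroid + (dx, dy, dz)
                best = max(best, np.mean(np.sum((coords - c) ** 2, 1) <= r**2))
    return float(best)


class TestSphericalness:
    def test_ball_close_to_one(self):
        seg = ellipsoid_mask((2.5, 2.5, 2.5), spacing=0.2)
        assert sphericalness(seg) >= 0.95

    def test_long_rod_far_from_sphere(self):
        seg = ellipsoid_mask((10.0, 0.5, 0.5), spacing=0.1)
        val = sphericalness(seg)
        assert val < 0.4
        assert val >= brute_force_sphericalness(seg, grid_step=1.0) - 1e-9

    def test_rigid_motion_invariance(self):
        a = sphericalness(ellipsoid_mask((3.0, 1.5, 1.5), 0.15))
        b = sphericalness(ellipsoid_mask((3.0, 1.5, 1.5), 0.15, angle_deg=30.0))
        assert abs(a - b) <= 0.02


class TestTumorLocation:
    def test_phantom_offset_recovered(self, tumor_result_50, tumor_phantom_50):
        res, truth = tumor_result_50
        mt = truth.mice[0]
        expected = res.segmentation.centroid_mm() - mt.landmarks["back_tooth"]
        # straight pose: the standard head frame is axis-aligned
        measured = tumor_location(res.segmentation, res.teeth)
        assert np.linalg.norm(measured - expected) < 1.0

    def test_translation_equivariance(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[4:8, 4:8, 4:8] = True
        seg_a = TumorSegmentation(mask, mask.sum() * 0.064, "right", 0.4, np.zeros(3))
        shifted = np.roll(mask, (5, 0, 0), axis=(0, 1, 2))
        seg_b = TumorSegmentation(shifted, mask.sum() * 0.064, "right", 0.4, np.zeros(3))

        class FakeTeeth:
            front_mm = np.array([0.0, -3.0, 0.0])
            back_mm = np.array([0.0, 3.0, 0.0])

        da = tumor_location(seg_a, FakeTeeth())
        db = tumor_location(seg_b, FakeTeeth())
        # translation along +x appears as a pure lateral offset of 5 voxels
        assert db - da == pytest.approx([5 * 0.4, 0.0, 0.0], abs=1e-9)

    def test_empty_mask_rejected(self):
        seg = TumorSegmentation(
            np.zeros((5, 5, 5), dtype=bool), 0.0, "right", 0.4, np.zeros(3)
        )

        class FakeTeeth:
            front_mm = np.array([0.0, -3.0, 0.0])
            back_mm = np.array([0.0, 3.0, 0.0])

        with pytest.raises(ValueError):
            tumor_location(seg, FakeTeeth())
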