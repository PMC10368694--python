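"""Curvilinear grid: construction, volumes, resampling, mirror refinement."""

import warnings

import numpy as np
import pytest

from mousecbct.anatomy import build_symmetry_chain, segment_bone, segment_teeth
from mousecbct.phantom import make_mouse_phantom
from mousecbct.symmetry import (
    CurvilinearGrid,
    GridError,
    build_grid,
    compute_voxel_volumes,
    refine_grid,
    resample_head,
)
from mousecbct.voxcore import ScanVolume, grid_total_volume


def chain_for(vol):
    teeth = segment_teeth(vol)
    return build_symmetry_chain(segment_bone(vol, teeth), teeth)


def identity_grid_for(vol):
    """Grid whose sample points are exactly the volume's voxel centers."""
    s = vol.spacing_mm
    shape = vol.shape
    j = shape[1] if shape[1] % 2 == 1 else shape[1] - 1
    axes = [vol.origin_mm[d] + (np.arange(n) + 0.5) * s for d, n in
            enumerate((shape[0], j, shape[2]))]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return CurvilinearGrid(pts, s)


@pytest.fixture(scope="module")
def straight_noiseless():
    return make_mouse_phantom(seed=1, noise_sigma=0.0)


@pytest.fixture(scope="module")
def bent_noiseless():
    return make_mouse_phantom(seed=1, bend_deg=20.0, noise_sigma=0.0)


class TestBuildGrid:
    def test_straight_chain_gives_rigid_grid_with_uniform_cells(self, straight_noiseless):
        vol, _ = straight_noiseless
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        vv = compute_voxel_volumes(grid)
        assert np.allclose(vv, vol.spacing_mm**3, atol=1e-6)

    def test_bent_grid_follows_the_neck(self, bent_noiseless):
        vol, _ = bent_noiseless
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        head = resample_head(vol, grid)
        # the resampled head is symmetric: tooth columns centered on midline
        from mousecbct.phantom import TOOTH
        teeth = head.data >= 0.9 * TOOTH
        assert teeth.any()
        j_com = np.argwhere(teeth)[:, 1].mean()
        assert abs(j_com - head.mid_index) < 1.5

    def test_space_counted_once_in_any_pose(
        self, straight_noiseless, bent_noiseless
    ):
        """The signed cell volumes count all real space exactly once: even
        though individual cells at the neck stitch fold (negative) or
        stretch severalfold, the mean signed cell volume stays the nominal
        voxel volume in every pose (< 2% deviation; exact when straight)."""
        means = []
        for vol, _ in (straight_noiseless, bent_noiseless):
            grid = build_grid(chain_for(vol), vol.spacing_mm)
            vv = compute_voxel_volumes(grid)
            means.append(float(vv.mean()) / vol.spacing_mm**3)
        assert means[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(means[1] - means[0]) < 0.02
        # the bent lattice really does fold and stretch at the stitch
        vol, _ = bent_noiseless
        vv = compute_voxel_volumes(build_grid(chain_for(vol), vol.spacing_mm))
        assert vv.min() < 0 < vv.max()

    def test_mirrored_chain_gives_j_reflected_grid(self, straight_noiseless):
        vol, _ = straight_noiseless
        chain = chain_for(vol)
        grid = build_grid(chain, vol.spacing_mm)

        import copy

        mirrored = copy.deepcopy(chain)
        for node in mirrored.nodes:
            for attr in ("mid_mm", "left_mm", "right_mm"):
                p = getattr(node, attr).copy()
                p[0] = -p[0]
                setattr(node, attr, p)
            node.left_mm, node.right_mm = node.right_mm, node.left_mm
        grid_m = build_grid(mirrored, vol.spacing_mm)
        p = grid.sample_points
        q = grid_m.sample_points[:, ::-1, :, :].copy()
        q[..., 0] = -q[..., 0]
        assert np.allclose(p, q, atol=1e-9)

    def test_even_lateral_dimension_rejected(self, straight_noiseless):
        vol, _ = straight_noiseless
        with pytest.raises(GridError):
            build_grid(chain_for(vol), vol.spacing_mm, standard_shape=(40, 30, 20))

    def test_standard_shape_compresses_to_requested_lattice(self, straight_noiseless):
        vol, _ = straight_noiseless
        grid = build_grid(chain_for(vol), vol.spacing_mm, standard_shape=(30, 41, 21))
        assert grid.standard_shape == (30, 41, 21)


class TestVoxelVolumes:
    def test_identity_grid_cells_equal_voxel_volume(self, straight_noiseless):
        vol, _ = straight_noiseless
        grid = identity_grid_for(vol)
        vv = compute_voxel_volumes(grid)
        assert np.allclose(vv, vol.spacing_mm**3, atol=1e-9)

    def test_uniform_scaling_scales_cells_cubically(self, straight_noiseless):
        vol, _ = straight_noiseless
        grid = identity_grid_for(vol)
        scaled = grid.with_points(grid.sample_points * 1.7)
        vv = compute_voxel_volumes(scaled)
        assert np.allclose(vv, 1.7**3 * vol.spacing_mm**3, rtol=1e-9)

    def test_total_volume_invariant_under_smooth_warp(self):
        axes = [np.arange(n, dtype=float) for n in (10, 9, 8)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        rng = np.random.default_rng(0)
        warped = pts.copy()
        for a in range(3):
            coords = [pts[..., d] / (s - 1) for d, s in enumerate((10, 9, 8))]
            bump = np.sin(np.pi * coords[0]) * np.sin(np.pi * coords[1]) * np.sin(np.pi * coords[2])
            warped[..., a] += 0.3 * bump * np.cos(2 * np.pi * coords[a] + rng.uniform(0, 6))
        grid = CurvilinearGrid(warped, 1.0)
        # the dual cells cover each voxel's own cell including a half-voxel
        # halo beyond the outermost sample points: a 10x9x8 box
        box = 10.0 * 9.0 * 8.0
        identity_total = compute_voxel_volumes(CurvilinearGrid(pts, 1.0)).sum()
        assert identity_total == pytest.approx(box, rel=1e-12)
        total = compute_voxel_volumes(grid).sum()
        assert abs(total - box) / box < 0.005  # boundary extrapolation only
        # the primal cells keep the exact invariance
        assert grid_total_volume(warped) == pytest.approx(9.0 * 8.0 * 7.0, rel=1e-9)


class TestResampleHead:
    def test_identity_grid_reproduces_source_exactly(self, straight_noiseless):
        vol, _ = straight_noiseless
        grid = identity_grid_for(vol)
        head = resample_head(vol, grid)
        j = head.data.shape[1]
        # identical up to interpolation round-off at exactly-integer indices
        assert np.allclose(head.data, vol.data[:, :j, :], atol=1e-8)

    def test_symmetric_phantom_resamples_below_noise_floor(self):
        vol, _ = make_mouse_phantom(seed=3, noise_sigma=50.0)
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        grid = refine_grid(grid, vol, max_steps=8)
        head = resample_head(vol, grid)
        asym = np.abs(head.data - head.mirrored()).mean()
        assert asym < 2 * 50.0


class TestRefineGrid:
    def test_perturbed_grid_recovers_mirror_alignment(self):
        vol, _ = make_mouse_phantom(seed=3, noise_sigma=10.0)
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        s = vol.spacing_mm
        shape = grid.sample_points.shape
        # smooth one-voxel lateral displacement breaking the symmetry
        i = np.linspace(0, np.pi, shape[0])[:, None, None]
        k = np.linspace(0, np.pi, shape[2])[None, None, :]
        bump = np.sin(i) * np.sin(k)
        pts = grid.sample_points.copy()
        pts[..., 0] += s * bump
        perturbed = grid.with_points(pts)
        refined = refine_grid(perturbed, vol, max_steps=40, max_disp_mm=2 * s)
        losses = refined.refine_losses
        assert losses[-1] <= 0.2 * losses[0]

    def test_loss_is_monotone_nonincreasing(self, straight_noiseless):
        vol, _ = make_mouse_phantom(seed=4, bend_deg=12.0)
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        refined = refine_grid(grid, vol, max_steps=10)
        losses = refined.refine_losses
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_already_optimal_grid_unchanged(self, straight_noiseless):
        vol, _ = straight_noiseless  # noiseless and exactly symmetric
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        refined = refine_grid(grid, vol, max_steps=10)
        delta = np.abs(refined.sample_points - grid.sample_points).max()
        assert delta < 1e-3 * vol.spacing_mm

    def test_infinite_curvature_penalty_freezes_grid(self):
        vol, _ = make_mouse_phantom(seed=5, bend_deg=15.0)
        grid = build_grid(chain_for(vol), vol.spacing_mm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined = refine_grid(grid, vol, lambda_curv=1e9, max_steps=5)
        delta = np.abs(refined.sample_points - grid.sample_points).max()
        assert delta < 1e-6
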