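"""Curvilinear resampling grid: bend-following, left-right symmetric.

The symmetry chain defines a midline polyline from snout to shoulders.  A
local rigid frame (tangent, horizontal lateral, up) is attached to each
chain segment; frames are blended across a window around interior nodes and
the midline curve is re-integrated from the blended tangent, so the grid
bends smoothly with the neck instead of creasing.  Sampling the scan at the
grid points produces the head in a standard symmetric orientation where the
lattice index ``j`` mirrors about the midplane ``m = (J-1)/2`` — anatomical
left and right become ``j`` and ``2m - j``.

Because the bent grid's voxels represent unequal real-space volumes, a
per-voxel volume map is computed from the 24-tetrahedron cell decomposition
(dual lattice around each sample point); the map sums to the volume of the
covered region regardless of pose.

``refine_grid`` registers the resampled head against its own mirror image
by gradient descent on the grid displacements, with a curvature penalty on
the displacement field, achieving sub-voxel midline alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phantom as _ph
from .anatomy import SymmetryChain
from .voxcore import ScanVolume, cell_volumes

__all__ = [
    "GridError",
    "CurvilinearGrid",
    "HeadVolume",
    "build_grid",
    "refine_grid",
    "resample_head",
    "compute_voxel_volumes",
]


class GridError(RuntimeError):
    pass


@dataclass
class CurvilinearGrid:
    """Lattice of real-space sample points (mm) with mirror structure."""

    sample_points: np.ndarray  # (I, J, K, 3)
    lattice_spacing_mm: float
    chain: SymmetryChain | None = None
    displacement: np.ndarray | None = None  # refinement displacement, mm
    refine_losses: list[float] = field(default_factory=list)
    u_values: np.ndarray | None = None  # arc-length coordinate per axial index
    stitch_bands: list[tuple[float, float]] = field(default_factory=list)

    def stitch_slices(self) -> np.ndarray:
        """Boolean per axial index: True inside a chain-stitch wedge.

        At a stitch the two segments' mirror planes form a dihedral wedge in
        which mirror correspondence is undefined; these axial slices are
        excluded from the excess-tissue analysis.
        """
        if self.u_values is None or not self.stitch_bands:
            return np.zeros(self.sample_points.shape[0], dtype=bool)
        u = self.u_values
        bad = np.zeros(len(u), dtype=bool)
        for lo, hi in self.stitch_bands:
            bad |= (u >= lo) & (u <= hi)
        return bad

    def __post_init__(self) -> None:
        p = np.asarray(self.sample_points, dtype=float)
        if p.ndim != 4 or p.shape[-1] != 3:
            raise GridError("sample_points must be (I, J, K, 3)")
        if p.shape[1] % 2 == 0:
            raise GridError("lateral lattice dimension J must be odd")
        self.sample_points = p

    @property
    def standard_shape(self) -> tuple[int, int, int]:
        return self.sample_points.shape[:3]

    @property
    def mid_index(self) -> int:
        return (self.sample_points.shape[1] - 1) // 2

    def mirror_j(self, j: np.ndarray | int):
        return 2 * self.mid_index - j

    @property
    def cell_volumes(self) -> np.ndarray:
        return compute_voxel_volumes(self)

    def with_points(self, points: np.ndarray, **kw) -> "CurvilinearGrid":
        return CurvilinearGrid(
            points,
            self.lattice_spacing_mm,
            chain=self.chain,
            u_values=None if self.u_values is None else self.u_values.copy(),
            stitch_bands=list(self.stitch_bands),
            **kw,
        )


@dataclass
class HeadVolume:
    """Head resampled into the standard symmetric orientation."""

    data: np.ndarray  # (I, J, K)
    voxel_volumes: np.ndarray  # (I, J, K) mm^3
    grid: CurvilinearGrid

    @property
    def mid_index(self) -> int:
        return self.grid.mid_index

    @property
    def lattice_spacing_mm(self) -> float:
        return self.grid.lattice_spacing_mm

    def mirrored(self) -> np.ndarray:
        return self.data[:, ::-1, :]


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------


def _chain_frames(chain: SymmetryChain, u: np.ndarray):
    """Midline positions and orthonormal frames at arc-length samples ``u``.

    Each sample carries the rigid frame of the chain segment it falls in:
    midline positions lie exactly on the chain polyline and the lateral
    direction is exactly perpendicular to that segment's mirror plane.  The
    per-segment rigid grids are stitched sharply at the nodes; on the inside
    of a bend the lattice folds and on the outside it stretches, which the
    *signed* cell volumes account for (folded space carries negative volume
    and cancels its double count), so all real space is counted exactly
    once.
    """
    mids = chain.midline.copy()
    # the neck bends about a vertical axis, so the grid axis is horizontal:
    # project the midline to the plane at the chain's mean height (vertical
    # landmark scatter would otherwise curl the lattice sagittally)
    mids[:, 2] = mids[:, 2].mean()
    seg = np.diff(mids, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        raise GridError("degenerate chain (zero-length segment)")
    tan = seg / seg_len[:, None]
    knots = np.concatenate([[0.0], np.cumsum(seg_len)])

    seg_of_u = np.clip(np.searchsorted(knots, u, side="right") - 1, 0, len(tan) - 1)
    tangents = tan[seg_of_u]
    centers = mids[seg_of_u] + (u - knots[seg_of_u])[:, None] * tangents

    # lateral: horizontal, to the right of the tangent (+x when T = +y)
    lat = np.stack([tangents[:, 1], -tangents[:, 0], np.zeros(len(u))], axis=1)
    lat /= np.linalg.norm(lat, axis=1, keepdims=True)
    up = np.cross(lat, tangents)
    up /= np.linalg.norm(up, axis=1, keepdims=True)
    return centers, tangents, lat, up


def build_grid(
    chain: SymmetryChain,
    spacing_mm: float,
    standard_shape: tuple[int, int, int] | None = None,
    lateral_halfwidth_mm: float = 14.0,
    vertical_range_mm: tuple[float, float] = (-7.5, 5.5),
    u_margin_mm: tuple[float, float] = (2.5, 2.0),
) -> CurvilinearGrid:
    """Build the curvilinear grid around a symmetry chain.

    Without ``standard_shape`` the lattice spans the chain's own arc length
    at unit scale (a straight chain yields a rigid map with all cell volumes
    equal to ``spacing_mm**3``).  With ``standard_shape`` the axial extent is
    linearly compressed/stretched so every mouse spans the same number of
    lattice planes regardless of body length.
    """
    s = float(spacing_mm)
    L = float(chain.segment_lengths_mm.sum())
    u_lo, u_hi = -u_margin_mm[0], L + u_margin_mm[1]
    if standard_shape is None:
        n_i = int(round((u_hi - u_lo) / s)) + 1
        u = u_lo + np.arange(n_i) * s
        half_j = int(round(lateral_halfwidth_mm / s))
        n_j = 2 * half_j + 1
        v = (np.arange(n_j) - half_j) * s
        n_k = int(round((vertical_range_mm[1] - vertical_range_mm[0]) / s)) + 1
        w = vertical_range_mm[0] + np.arange(n_k) * s
    else:
        n_i, n_j, n_k = standard_shape
        if n_j % 2 == 0:
            raise GridError("standard_shape J must be odd")
        u = np.linspace(u_lo, u_hi, n_i)
        v = (np.arange(n_j) - (n_j - 1) // 2) * s
        w = np.linspace(vertical_range_mm[0], vertical_range_mm[1], n_k)

    centers, tangents, lat, up = _chain_frames(chain, u)
    pts = (
        centers[:, None, None, :]
        + lat[:, None, None, :] * v[None, :, None, None]
        + up[:, None, None, :] * w[None, None, :, None]
    )

    # dihedral wedges at the chain stitches: between two segments' mirror
    # planes no mirror correspondence exists out to the tissue halfwidth.
    # Arc length and wedge angles follow the horizontally projected midline,
    # matching the frame construction.
    mids = chain.midline.copy()
    mids[:, 2] = 0.0
    seg_vec = np.diff(mids, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    knots = np.concatenate([[0.0], np.cumsum(seg_len)])
    seg_dir = seg_vec / seg_len[:, None]
    bands = []
    tissue_halfwidth = 6.0
    for k in range(1, len(knots) - 1):
        cosang = float(np.clip(seg_dir[k - 1] @ seg_dir[k], -1.0, 1.0))
        ang = np.arccos(cosang)
        if ang > np.deg2rad(1.0):
            half = tissue_halfwidth * np.tan(ang) + 1.5 * s
            bands.append((float(knots[k] - half), float(knots[k] + half)))

    grid = CurvilinearGrid(
        pts, s, chain=chain, u_values=u, stitch_bands=bands
    )
    compute_voxel_volumes(grid)  # validates (raises on gross self-intersection)
    return grid


def compute_voxel_volumes(grid: CurvilinearGrid) -> np.ndarray:
    """Per-voxel real-space volumes (mm^3) of the grid lattice.

    Each lattice voxel's cell is the dual cell around its sample point
    (corners at neighbor midpoints, extrapolated at the lattice boundary),
    evaluated with the 24-tetrahedron decomposition.  Volumes are *signed*:
    where the lattice folds at a chain-segment stitch, real space is sampled
    more than once, and the folded cells' negative volumes cancel the double
    count so the total equals the covered region's volume exactly.  A grid
    whose negative-volume fraction is large is self-intersecting beyond any
    stitch fold and rejected.
    """
    p = grid.sample_points
    dual = p
    for axis in range(3):
        mid = 0.5 * (
            np.take(dual, np.arange(dual.shape[axis] - 1), axis=axis)
            + np.take(dual, np.arange(1, dual.shape[axis]), axis=axis)
        )
        first = 2.0 * np.take(dual, [0], axis=axis) - np.take(mid, [0], axis=axis)
        last = 2.0 * np.take(dual, [-1], axis=axis) - np.take(mid, [-1], axis=axis)
        dual = np.concatenate([first, mid, last], axis=axis)
    vols = cell_volumes(dual)
    # normalize lattice handedness: a consistently oriented grid has one
    # global sign; only sign *changes* indicate folds
    if np.median(vols) < 0:
        vols = -vols
    neg = -vols[vols < 0].sum()
    if neg > 0.2 * vols[vols > 0].sum():
        raise GridError("grid is self-intersecting (large negative volume)")
    return vols


# ---------------------------------------------------------------------------
# Resampling and mirror refinement
# ---------------------------------------------------------------------------


def _sample(vol: ScanVolume, points: np.ndarray, cval: float = _ph.AIR) -> np.ndarray:
    idx = (points - vol.origin_mm) / vol.spacing_mm - 0.5
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        vol.data.astype(np.float64), coords, order=1, mode="constant", cval=cval
    )


def resample_head(vol: ScanVolume, grid: CurvilinearGrid) -> HeadVolume:
    """Trilinearly resample the scan at the grid points (out of volume -> air)."""
    data = _sample(vol, grid.sample_points)
    return HeadVolume(data.astype(np.float32), compute_voxel_volumes(grid), grid)


def _laplacian(a: np.ndarray) -> np.ndarray:
    """Discrete 6-neighbor Laplacian with edge replication, per component."""
    out = np.zeros_like(a)
    for axis in range(3):
        hi = np.concatenate(
            [np.take(a, np.arange(1, a.shape[axis]), axis=axis),
             np.take(a, [-1], axis=axis)], axis=axis)
        lo = np.concatenate(
            [np.take(a, [0], axis=axis),
             np.take(a, np.arange(a.shape[axis] - 1), axis=axis)], axis=axis)
        out += hi + lo - 2.0 * a
    return out


def refine_grid(
    grid: CurvilinearGrid,
    vol: ScanVolume,
    lambda_curv: float = 0.1,
    max_steps: int = 30,
    smooth_sigma: float = 2.0,
    rel_tol: float = 1e-5,
    max_disp_mm: float | None = None,
) -> CurvilinearGrid:
    """Register the head with its own mirror image by gradient descent.

    Minimizes ``mean((H - mirror_j(H))^2) / norm0 + lambda_curv *
    mean(|Laplacian(D)|^2) / s^2`` over a smooth displacement field ``D`` of
    the grid points, where ``H`` is the head resampled through the displaced
    grid and ``norm0`` normalizes the data term to 1 at the start.  The
    gradient is computed analytically (chain rule through the trilinear
    interpolation) and smoothed with a Gaussian of ``smooth_sigma`` lattice
    units, restricting updates to a coarse, smooth control field.  Steps are
    accepted only if the loss decreases (backtracking line search), so the
    reported loss sequence is monotone non-increasing.

    ``max_disp_mm`` caps the displacement per component (default one lattice
    voxel): the registration corrects sub-voxel midline misalignment and
    must not be free to flatten genuine one-sided anatomy — a unilateral
    tumor *is* mirror asymmetry, and an unconstrained registration would
    absorb it.
    """
    base = grid.sample_points
    s = grid.lattice_spacing_mm
    sp = vol.spacing_mm
    data64 = ndimage.gaussian_filter(vol.data.astype(np.float64), 1.0)
    grads = np.stack(np.gradient(data64, sp), axis=-1)

    def head_at(D):
        return _sample(vol, base + D)

    # register only where tissue is present on BOTH sides of the midline:
    # one-sided excess (a tumor) is the signal downstream stages measure and
    # must not be absorbed by the registration
    H0 = head_at(np.zeros_like(base))
    tis = H0 >= 0.5 * _ph.SOFT_TISSUE
    w = (tis & tis[:, ::-1, :]).astype(np.float64)
    if w.sum() < 1:
        w = np.ones_like(H0)
    n_w = float(w.sum())

    def sample_grads(P):
        idx = (P - vol.origin_mm) / sp - 0.5
        coords = np.moveaxis(idx, -1, 0)
        return np.stack(
            [
                ndimage.map_coordinates(grads[..., c], coords, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )

    def data_term(H):
        diff = H - H[:, ::-1, :]
        return float(np.sum(w * diff**2) / n_w), diff

    D = np.zeros_like(base)
    H = H0
    d0, _ = data_term(H)
    norm0 = max(d0, 1e-12)

    def loss(D, H):
        dterm, diff = data_term(H)
        lap = _laplacian(D)
        curv = float(np.mean(np.sum(lap**2, axis=-1))) / s**2
        return dterm / norm0 + lambda_curv * curv, diff, lap

    cur, diff, lap = loss(D, H)
    losses = [cur]
    step = 0.25 * s
    cap = s if max_disp_mm is None else float(max_disp_mm)
    accepted_any = False
    for _ in range(max_steps):
        # analytic gradient of the mirror data term
        dL_dH = (2.0 / (n_w * norm0)) * w * (diff - diff[:, ::-1, :])
        g = dL_dH[..., None] * sample_grads(base + D)
        g += lambda_curv * (2.0 / (D[..., 0].size * s**2)) * _laplacian(lap)
        for c in range(3):
            g[..., c] = ndimage.gaussian_filter(g[..., c], smooth_sigma, mode="nearest")
        gmax = np.abs(g).max()
        if gmax == 0:
            break
        improved = False
        trial_step = step
        for _ in range(10):
            D_new = np.clip(D - (trial_step / gmax) * g, -cap, cap)
            H_new = head_at(D_new)
            new, diff_new, lap_new = loss(D_new, H_new)
            if new < cur:
                improved = True
                break
            trial_step *= 0.5
        if not improved:
            if not accepted_any:
                warnings.warn("mirror refinement made no progress; grid unchanged")
                return grid.with_points(base.copy(), refine_losses=losses)
            break
        accepted_any = True
        rel = (cur - new) / max(cur, 1e-12)
        D, H, cur, diff, lap = D_new, H_new, new, diff_new, lap_new
        losses.append(cur)
        step = min(trial_step * 1.5, s)
        if rel < rel_tol:
            break

    refined = grid.with_points(base + D, refine_losses=losses)
    refined.displacement = D
    compute_voxel_volumes(refined)  # validate
    return refined
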