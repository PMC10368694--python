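"""Symmetry-based buccal tumor segmentation and shape analytics.

In the resampled symmetric head, tissue on the healthy side maps trivially
onto the tumor side through the lattice mirror, so a unilateral cheek tumor
appears as excess one-sided tissue.  Per sagittal column the excess tissue
volume is accumulated into a 2-D height map, which is filtered (median,
Gaussian, thickness threshold, largest connected region) and back-projected
through the curvilinear grid into the original scan to produce a 3-D tumor
mask.  Tumor volume is the sum of the marked lattice voxels' real-space
cell volumes.

Shape analytics follow: the eigendecomposition of the tumor voxel-coordinate
covariance (principal axes and normalized eigenvalues), the uniform-ellipsoid
volume implied by those eigenvalues, the sphericalness (fraction of the
tumor inside an equal-volume sphere) and the centroid offset from the back
tooth landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phantom as _ph
from .anatomy import ToothLandmarks
from .symmetry import CurvilinearGrid, HeadVolume
from .voxcore import ScanVolume

__all__ = [
    "HeightMap",
    "TumorSegmentation",
    "ShapeMetrics",
    "excess_height_map",
    "filter_height_map",
    "backproject_tumor",
    "shape_eigen",
    "ellipsoid_volume",
    "sphericalness",
    "tumor_location",
]

TISSUE_HALF_MAX = 0.5 * _ph.SOFT_TISSUE


@dataclass
class HeightMap:
    """Excess one-sided tissue per sagittal column of the head lattice.

    ``values[i, k]`` is the excess tissue volume (mm^3) in the column at
    axial index i and vertical index k; dividing by the lattice column
    footprint (``lattice_spacing**2``) gives a thickness equivalent in mm.
    """

    values: np.ndarray  # (I, K)
    side: str
    lattice_spacing_mm: float
    filtered: bool = False

    def thickness_mm(self) -> np.ndarray:
        return self.values / self.lattice_spacing_mm**2

    def total_mm3(self) -> float:
        return float(self.values.sum())


@dataclass
class TumorSegmentation:
    """Tumor voxel mask in original scan coordinates, with provenance."""

    mask: np.ndarray  # scan-space bool
    volume_mm3: float
    side: str
    spacing_mm: float
    origin_mm: np.ndarray
    lattice_mask: np.ndarray | None = None  # marked head-lattice voxels
    mouse_id: str = ""
    scan_date: str = ""

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def centroid_mm(self) -> np.ndarray:
        if not self.mask.any():
            raise ValueError("empty tumor mask has no centroid")
        idx = np.argwhere(self.mask)
        return self.origin_mm + (idx.mean(axis=0) + 0.5) * self.spacing_mm


@dataclass
class ShapeMetrics:
    eigenvalues_mm2: np.ndarray  # descending
    normalized: np.ndarray  # sqrt(eig) / sum(sqrt(eig))
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    centroid_mm: np.ndarray


def excess_height_map(head: HeadVolume, tumor_side: str = "right") -> HeightMap:
    """Initial height map: tissue volume on the tumor side minus the mirror.

    Tissue is intensity at or above the soft-tissue half-maximum, weighted
    by per-voxel real-space volumes.  Negative values (more tissue on the
    healthy side) are retained in the initial map.
    """
    if tumor_side not in ("left", "right"):
        raise ValueError("tumor_side must be 'left' or 'right'")
    m = head.mid_index
    tissue = (head.data >= TISSUE_HALF_MAX).astype(np.float64) * head.voxel_volumes
    right = tissue[:, m + 1 :, :].sum(axis=1)
    left = tissue[:, :m, :].sum(axis=1)
    excess = right - left if tumor_side == "right" else left - right
    # no mirror correspondence exists inside a chain-stitch wedge
    excess[head.grid.stitch_slices(), :] = 0.0
    return HeightMap(excess, tumor_side, head.lattice_spacing_mm)


def filter_height_map(
    hm: HeightMap,
    min_thickness_mm: float = 0.4,
    smooth_mm: float = 0.3,
) -> HeightMap:
    """2-D processing of the initial height map into a tumor footprint.

    Negatives are clamped, a 3x3 median filter removes speckle, Gaussian
    smoothing (sigma ``smooth_mm``) regularizes edges, columns thinner than
    ``min_thickness_mm`` are zeroed, and only the largest connected 2-D
    region survives (unilateral single-tumor model).  An all-zero result is
    a valid no-tumor outcome.
    """
    s = hm.lattice_spacing_mm
    v = np.clip(hm.values, 0.0, None)
    v = ndimage.median_filter(v, size=3, mode="nearest")
    if smooth_mm > 0:
        v = ndimage.gaussian_filter(v, smooth_mm / s, mode="nearest")
    v[v < min_thickness_mm * s**2] = 0.0
    if v.any():
        labels, n = ndimage.label(v > 0)
        if n > 1:
            areas = ndimage.sum_labels(np.ones_like(v), labels, np.arange(1, n + 1))
            keep = int(np.argmax(areas)) + 1
            v[labels != keep] = 0.0
    return HeightMap(v, hm.side, s, filtered=True)


def backproject_tumor(
    hm: HeightMap,
    grid: CurvilinearGrid,
    head: HeadVolume,
    scan: ScanVolume,
    mouse_id: str = "",
    scan_date: str = "",
) -> TumorSegmentation:
    """Mark the excess outer tissue voxels and map them back to the scan.

    For each nonzero height-map column, the outermost tissue voxels on the
    tumor side are marked down to the depth matched by tissue on the mirror
    side; marked lattice voxels are carried through the grid into original
    scan coordinates.  The volume is accounted in lattice space with the
    per-voxel real-space cell volumes.
    """
    m = head.mid_index
    tissue = head.data >= TISSUE_HALF_MAX
    if hm.side == "right":
        tum = tissue[:, m + 1 :, :][:, ::-1, :]  # outermost first
        ref = tissue[:, :m, :]
    else:
        tum = tissue[:, :m, :]  # j=0 is outermost on the left
        ref = tissue[:, m + 1 :, :][:, ::-1, :]
    n_t = tum.sum(axis=1)
    n_m = ref.sum(axis=1)
    n_excess = np.where(hm.values > 0, np.clip(n_t - n_m, 0, None), 0)
    rank = np.cumsum(tum, axis=1)  # rank of each tissue voxel from outside
    marked_out = tum & (rank <= n_excess[:, None, :])
    lattice_mask = np.zeros(head.data.shape, dtype=bool)
    if hm.side == "right":
        lattice_mask[:, m + 1 :, :] = marked_out[:, ::-1, :]
    else:
        lattice_mask[:, :m, :] = marked_out

    volume = float(head.voxel_volumes[lattice_mask].sum())

    scan_mask = np.zeros(scan.shape, dtype=bool)
    if lattice_mask.any():
        pts = grid.sample_points[lattice_mask]
        idx = np.round((pts - scan.origin_mm) / scan.spacing_mm - 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(scan.shape)), axis=1)
        idx = idx[ok]
        scan_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        # close sub-voxel cracks left by the lattice -> scan rounding
        scan_mask = ndimage.binary_closing(
            scan_mask, structure=ndimage.generate_binary_structure(3, 1)
        )
    return TumorSegmentation(
        scan_mask,
        volume,
        hm.side,
        scan.spacing_mm,
        scan.origin_mm.copy(),
        lattice_mask=lattice_mask,
        mouse_id=mouse_id,
        scan_date=scan_date,
    )


def _mask_coords_mm(seg) -> tuple[np.ndarray, float]:
    """Voxel-center coordinates (mm) and voxel volume of a segmentation/mask."""
    if isinstance(seg, TumorSegmentation):
        idx = np.argwhere(seg.mask)
        coords = seg.origin_mm + (idx + 0.5) * seg.spacing_mm
        return coords, seg.spacing_mm**3
    # duck-typed: objects with .data boolean and .spacing_mm
    idx = np.argwhere(np.asarray(seg.data, dtype=bool))
    coords = (idx + 0.5) * seg.spacing_mm
    return coords, seg.spacing_mm**3


def shape_eigen(seg) -> ShapeMetrics:
    """Eigendecomposition of the tumor voxel-coordinate covariance.

    The covariance of voxel-center coordinates about the centroid (all
    voxels carry the same real-space volume, so this is volume-weighted) is
    diagonalized; eigenvalues are sorted descending and normalized by the
    square-root-then-sum rule: ``e_i = sqrt(l_i) / sum_j sqrt(l_j)``.
    """
    coords, _ = _mask_coords_mm(seg)
    if len(coords) < 4:
        raise ValueError("need >= 4 tumor voxels for shape analysis")
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 0:
        raise ValueError("degenerate (coplanar) tumor mask")
    roots = np.sqrt(evals)
    return ShapeMetrics(evals, roots / roots.sum(), evecs, centroid)


def ellipsoid_volume(metrics: ShapeMetrics) -> float:
    """Volume (mm^3) of the uniform solid ellipsoid with these eigenvalues.

    A uniform ellipsoid with semi-axes (A, B, C) has coordinate covariance
    eigenvalues (A^2, B^2, C^2)/5, so the implied volume is
    ``(4 pi / 3) * 5^(3/2) * sqrt(l1 l2 l3)``.
    """
    return float(4.0 * np.pi / 3.0 * 5.0**1.5 * np.sqrt(np.prod(metrics.eigenvalues_mm2)))


def sphericalness(seg, search_vox: int = 2) -> float:
    """Fraction of the tumor that fits in a sphere of the tumor's volume.

    The sphere has the radius of the equal-volume ball; its center starts at
    the mask centroid and is locally searched over +/- ``search_vox`` voxel
    steps to maximize inclusion.
    """
    coords, voxvol = _mask_coords_mm(seg)
    if len(coords) == 0:
        raise ValueError("empty tumor mask")
    spacing = voxvol ** (1.0 / 3.0)
    volume = len(coords) * voxvol
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    centroid = coords.mean(axis=0)
    best = 0.0
    offs = np.arange(-search_vox, search_vox + 1) * spacing
    for dx in offs:
        for dy in offs:
            for dz in offs:
                c = centroid + (dx, dy, dz)
                inside = np.sum(np.sum((coords - c) ** 2, axis=1) <= r**2)
                best = max(best, inside / len(coords))
    return float(best)


def tumor_location(
    seg: TumorSegmentation, teeth: ToothLandmarks
) -> np.ndarray:
    """Tumor centroid offset from the back-tooth landmark (mm).

    Expressed in standard head coordinates: (lateral, along head axis,
    vertical), with the head axis taken from the front-to-back tooth line.
    """
    centroid = seg.centroid_mm()
    axis = teeth.back_mm - teeth.front_mm
    e_ap = axis / np.linalg.norm(axis)
    e_lat = np.array([e_ap[1], -e_ap[0], 0.0])
    e_lat /= np.linalg.norm(e_lat)
    e_up = np.cross(e_lat, e_ap)
    d = centroid - teeth.back_mm
    return np.array([d @ e_lat, d @ e_ap, d @ e_up])
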