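"""Volumetric primitives shared by every pipeline stage.

The universal image container is :class:`ScanVolume`: a 3-D scalar array with
isotropic voxel spacing and a fixed axis convention

* axis 0 — ``x``, lateral (the splitting axis; mouse left/right),
* axis 1 — ``y``, anterior–posterior (snout at low ``y``),
* axis 2 — ``z``, vertical (bed at low ``z``).

Voxel indices are 0-based; voxel ``(i, j, k)`` owns the half-open real-space
cube ``[i, i+1) x [j, j+1) x [k, k+1)`` in units of ``spacing_mm`` from
``origin_mm``, so its center sits at ``origin + (index + 0.5) * spacing``.

Besides masks and connected components, this module implements exact volume
accounting for deformed (curvilinear) voxel grids: each hexahedral cell is
decomposed into 24 tetrahedra (6 faces x 4 triangles per face, every triangle
joined to the face centroid and the cell centroid), a construction that tiles
any non-degenerate hexahedron exactly once, so summed cell volumes conserve
the volume of the region the grid covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ScanVolume",
    "BinaryMask",
    "LabeledMask",
    "threshold_mask",
    "connected_components",
    "hexa_cell_volume",
    "cell_volumes",
    "grid_total_volume",
    "max_intensity_projection",
]

_AXIS_NAMES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class ScanVolume:
    """3-D intensity grid with isotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("ScanVolume data must be 3-D with shape >= 2 per axis")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm) ** 3

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Real-space centers (mm) of voxels given an (N, 3) index array."""
        return self.origin_mm + (np.asarray(indices, dtype=float) + 0.5) * self.spacing_mm

    def index_of_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel index coordinates of real-space points (mm)."""
        return (np.asarray(points_mm, dtype=float) - self.origin_mm) / self.spacing_mm - 0.5

    def copy(self) -> "ScanVolume":
        return ScanVolume(self.data.copy(), self.spacing_mm, self.origin_mm.copy())


@dataclass
class BinaryMask:
    """Boolean mask congruent with a parent :class:`ScanVolume`."""

    data: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * float(self.spacing_mm) ** 3


@dataclass
class LabeledMask:
    """Connected-component labeling; 0 = background, labels contiguous 1..K."""

    data: np.ndarray
    component_sizes: dict[int, int]
    spacing_mm: float = 1.0

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    def component(self, label: int) -> np.ndarray:
        return self.data == label

    def largest_label(self) -> int:
        if not self.component_sizes:
            raise ValueError("no components")
        return max(self.component_sizes, key=lambda k: (self.component_sizes[k], -k))


def threshold_mask(vol: ScanVolume, low: float, high: float) -> BinaryMask:
    """Mask of voxels whose intensity lies in the closed band ``[low, high]``."""
    if low > high:
        raise ValueError(f"invalid threshold range: low={low} > high={high}")
    return BinaryMask((vol.data >= low) & (vol.data <= high), vol.spacing_mm)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabeledMask:
    """Label connected components of a binary mask.

    Labels are assigned deterministically in first-voxel raster-scan order:
    the component whose first voxel (flattened C-order index) comes first is
    label 1, and so on.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of {6, 18, 26}")
    raw, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    if n == 0:
        return LabeledMask(raw, {}, mask.spacing_mm)
    flat = raw.ravel()
    # order labels by first occurrence in scan order
    nz = np.flatnonzero(flat)
    first_seen_labels = flat[nz]
    _, first_idx = np.unique(first_seen_labels, return_index=True)
    order = first_seen_labels[np.sort(first_idx)]
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[order] = np.arange(1, n + 1)
    relabeled = remap[raw]
    sizes = np.bincount(relabeled.ravel(), minlength=n + 1)
    component_sizes = {int(lbl): int(sizes[lbl]) for lbl in range(1, n + 1)}
    return LabeledMask(relabeled, component_sizes, mask.spacing_mm)


# ---------------------------------------------------------------------------
# Exact volume accounting for deformed voxel cells
# ---------------------------------------------------------------------------

# Corner index convention (z-fastest): corner c = 4*i + 2*j + k for
# (i, j, k) in {0, 1}^3.  Face loops are ordered so their normals point
# outward for an axis-aligned cell; orientation is validated by the unit-cube
# identity in the test suite.
_FACE_LOOPS = np.array(
    [
        [0, 1, 3, 2],  # x-
        [4, 6, 7, 5],  # x+
        [0, 4, 5, 1],  # y-
        [2, 3, 7, 6],  # y+
        [0, 2, 6, 4],  # z-
        [1, 5, 7, 3],  # z+
    ]
)


def _hexa_volumes(corners: np.ndarray) -> np.ndarray:
    """Signed volumes of hexahedral cells given corners of shape (..., 8, 3).

    Sum of 24 signed tetrahedra: for each face, the 4 triangles fanning the
    face centroid, each joined to the cell centroid.
    """
    corners = np.asarray(corners, dtype=float)
    cc = corners.mean(axis=-2)  # (..., 3) cell centroid
    total = np.zeros(corners.shape[:-2])
    for loop in _FACE_LOOPS:
        face = corners[..., loop, :]  # (..., 4, 3)
        fc = face.mean(axis=-2)  # face centroid
        a = fc - cc
        for t in range(4):
            b = face[..., t, :] - cc
            c = face[..., (t + 1) % 4, :] - cc
            total = total + np.einsum("...i,...i->...", a, np.cross(b, c))
    return total / 6.0


def hexa_cell_volume(corners: np.ndarray) -> float:
    """Volume (mm^3) of one deformed voxel cell from its 8 corner points.

    ``corners`` is (8, 3) in the z-fastest corner order (corner ``4i+2j+k``
    is the corner at offset ``(i, j, k)``).  A fully degenerate (coplanar)
    cell returns 0.0 rather than raising.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (8, 3):
        raise ValueError("corners must have shape (8, 3)")
    return float(_hexa_volumes(corners))


def cell_volumes(sample_points: np.ndarray) -> np.ndarray:
    """Per-cell volumes (mm^3) for a lattice of real-space sample points.

    ``sample_points`` has shape (I, J, K, 3); the result has shape
    (I-1, J-1, K-1), one signed volume per hexahedral cell.
    """
    p = np.asarray(sample_points, dtype=float)
    if p.ndim != 4 or p.shape[-1] != 3 or min(p.shape[:3]) < 2:
        raise ValueError("sample_points must be (I, J, K, 3) with >= 2 points per axis")
    corners = np.empty(tuple(s - 1 for s in p.shape[:3]) + (8, 3))
    c = 0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners[..., c, :] = p[
                    di : p.shape[0] - 1 + di,
                    dj : p.shape[1] - 1 + dj,
                    dk : p.shape[2] - 1 + dk,
                ]
                c += 1
    return _hexa_volumes(corners)


def grid_total_volume(grid) -> float:
    """Total real-space volume (mm^3) covered by a curvilinear grid.

    Accepts either an (I, J, K, 3) array of sample points or any object with
    a ``sample_points`` attribute.  Because the 24-tetrahedron decomposition
    tiles each cell exactly once, the total is invariant under any smooth
    re-indexing (warp) of the same region.
    """
    points = getattr(grid, "sample_points", grid)
    return float(cell_volumes(points).sum())


def max_intensity_projection(vol: ScanVolume, axis: str | int) -> np.ndarray:
    """Maximum intensity projection along ``axis`` ('x', 'y' or 'z')."""
    if axis not in _AXIS_NAMES:
        raise ValueError(f"invalid axis {axis!r}")
    return vol.data.max(axis=_AXIS_NAMES[axis])
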