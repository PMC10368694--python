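"""Skeletal landmarks anchoring the head-symmetry coordinate system.

Teeth are the most reliable anatomy in a low-dose CBCT scan (their density
is far above everything else), so segmentation starts there: front, bottom
and back tooth clusters give three reproducible points.  Bone is then
thresholded and classified by position relative to the teeth into cranium,
jaw and the bilateral shoulder pair.  From these, a symmetry chain is built:
an ordered list of midline nodes, each paired with corresponding left and
right points, forming a polyline from snout to shoulders that can bend at
the neck while preserving segment lengths.  The chain is what the
curvilinear resampling grid is later wrapped around.

Scans are assumed to be in the standard prone orientation: snout toward low
y, bed toward low z (the orientation the multi-mouse holders enforce).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phantom as _ph
from .voxcore import BinaryMask, ScanVolume, connected_components, threshold_mask

__all__ = [
    "LandmarkError",
    "ToothLandmarks",
    "BoneSegmentation",
    "ChainNode",
    "SymmetryChain",
    "segment_teeth",
    "segment_bone",
    "build_symmetry_chain",
]

TOOTH_BAND = (0.85 * _ph.TOOTH, 1.15 * _ph.TOOTH)
BONE_BAND = (0.5 * (_ph.SOFT_TISSUE + _ph.BONE), 0.85 * _ph.TOOTH)
MIN_TOOTH_VOX_AT_01 = 20  # at 0.1 mm spacing; scaled by (0.1/spacing)^3

JAW, CRANIUM, SHOULDERS, OTHER = 1, 2, 3, 4
BONE_LABEL_NAMES = {JAW: "jaw", CRANIUM: "cranium", SHOULDERS: "shoulders", OTHER: "other"}


class LandmarkError(RuntimeError):
    pass


@dataclass
class ToothLandmarks:
    mask: BinaryMask
    front_mm: np.ndarray
    bottom_mm: np.ndarray
    back_mm: np.ndarray
    centroids_mm: np.ndarray  # all tooth cluster centroids

    def as_dict(self) -> dict[str, list[float]]:
        return {
            "front_tooth": list(map(float, self.front_mm)),
            "bottom_tooth": list(map(float, self.bottom_mm)),
            "back_tooth": list(map(float, self.back_mm)),
        }


@dataclass
class BoneSegmentation:
    labels: np.ndarray  # 0 background, else JAW/CRANIUM/SHOULDERS/OTHER
    spacing_mm: float
    origin_mm: np.ndarray
    counts: dict[str, int] = field(default_factory=dict)
    shoulder_centroids_mm: np.ndarray | None = None  # (2, 3), left then right

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ChainNode:
    mid_mm: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    name: str = ""


@dataclass
class SymmetryChain:
    """Snout-to-shoulders polyline with paired lateral points.

    Nodes are ordered anterior to posterior; consecutive midline points are
    monotone along the body axis.  ``|left - mid| == |right - mid|`` holds by
    construction (lateral points are symmetrized).
    """

    nodes: list[ChainNode]

    def __post_init__(self) -> None:
        if len(self.nodes) < 3:
            raise LandmarkError("symmetry chain needs at least 3 nodes")

    @property
    def midline(self) -> np.ndarray:
        return np.array([n.mid_mm for n in self.nodes])

    @property
    def segment_lengths_mm(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.midline, axis=0), axis=1)

    def fit_to_reference_lengths(self, ref_lengths_mm) -> "SymmetryChain":
        """Rescale each segment about its midpoint to match reference lengths.

        A few sweeps of per-segment midpoint scaling converge to a chain
        whose segment lengths equal the reference while node positions stay
        as close as possible to the detected landmarks.
        """
        ref = np.asarray(ref_lengths_mm, dtype=float)
        if len(ref) != len(self.nodes) - 1:
            raise ValueError("reference length count must match segment count")
        mids = self.midline.copy()
        for _ in range(20):
            for i in range(len(ref)):
                seg = mids[i + 1] - mids[i]
                length = np.linalg.norm(seg)
                if length == 0:
                    continue
                corr = 0.5 * (ref[i] - length) * seg / length
                mids[i] -= corr
                mids[i + 1] += corr
        nodes = []
        for node, mid in zip(self.nodes, mids):
            shift = mid - node.mid_mm
            nodes.append(
                ChainNode(mid, node.left_mm + shift, node.right_mm + shift, node.name)
            )
        return SymmetryChain(nodes)


def _min_tooth_voxels(spacing_mm: float) -> int:
    return max(1, int(round(MIN_TOOTH_VOX_AT_01 * (0.1 / spacing_mm) ** 3)))


def segment_teeth(vol: ScanVolume) -> ToothLandmarks:
    """Locate the three tooth clusters and their landmark points.

    Teeth are thresholded at the top intensity band, labeled with
    6-connectivity (keeps adjacent clusters separable) and speckle-filtered.
    The front tooth is the most anterior cluster centroid, the bottom tooth
    the most inferior, the back tooth the most posterior.
    """
    mask = threshold_mask(vol, *TOOTH_BAND)
    labels = connected_components(mask, connectivity=6)
    min_vox = _min_tooth_voxels(vol.spacing_mm)
    keep = [lbl for lbl, n in labels.component_sizes.items() if n >= min_vox]
    if not keep:
        raise LandmarkError("no tooth-class component found")
    coms = np.array(ndimage.center_of_mass(mask.data, labels.data, keep))
    coms_mm = vol.voxel_centers_mm(coms)
    front = coms_mm[np.argmin(coms_mm[:, 1])]
    bottom = coms_mm[np.argmin(coms_mm[:, 2])]
    back = coms_mm[np.argmax(coms_mm[:, 1])]
    clean = np.isin(labels.data, keep)
    return ToothLandmarks(
        BinaryMask(clean, vol.spacing_mm), front, bottom, back, coms_mm
    )


def segment_bone(vol: ScanVolume, teeth: ToothLandmarks) -> BoneSegmentation:
    """Segment bone and classify it into jaw, cranium and shoulders.

    Bone is the band between soft tissue and teeth.  Components are
    classified by position relative to the tooth landmarks: components well
    posterior of the back tooth form the bilateral shoulder pair; of the
    rest, the one nearest the bottom tooth is the jaw and the most superior
    large component is the cranium.
    """
    mask = threshold_mask(vol, *BONE_BAND)
    labels = connected_components(mask, connectivity=26)
    min_vox = _min_tooth_voxels(vol.spacing_mm)
    comps = [(lbl, n) for lbl, n in labels.component_sizes.items() if n >= min_vox]
    if not comps:
        raise LandmarkError("no bone-class component found")
    lbls = [c[0] for c in comps]
    coms = np.array(ndimage.center_of_mass(mask.data, labels.data, lbls))
    coms_mm = vol.voxel_centers_mm(coms)

    out = np.zeros(vol.shape, dtype=np.uint8)
    back_y = teeth.back_mm[1]
    bottom = teeth.bottom_mm
    is_shoulder = coms_mm[:, 1] > back_y + 4.0
    rest = np.flatnonzero(~is_shoulder)
    assigned = {}
    if rest.size:
        d_bottom = np.linalg.norm(coms_mm[rest] - bottom, axis=1)
        jaw_i = rest[np.argmin(d_bottom)]
        if d_bottom.min() < 5.0:
            assigned[lbls[jaw_i]] = JAW
        cran_candidates = [i for i in rest if lbls[i] not in assigned]
        if cran_candidates:
            sizes = np.array([labels.component_sizes[lbls[i]] for i in cran_candidates])
            zs = coms_mm[cran_candidates, 2]
            # cranium: superior envelope; prefer the largest superior component
            order = np.lexsort((sizes, zs))
            cran_i = cran_candidates[int(order[-1])]
            if coms_mm[cran_i, 2] > bottom[2]:
                assigned[lbls[cran_i]] = CRANIUM
    if CRANIUM not in assigned.values():
        raise LandmarkError("cranium not found")

    shoulder_idx = np.flatnonzero(is_shoulder)
    sh_centroids = None
    if shoulder_idx.size >= 2:
        sizes = np.array([labels.component_sizes[lbls[i]] for i in shoulder_idx])
        two = shoulder_idx[np.argsort(sizes)[::-1][:2]]
        for i in two:
            assigned[lbls[i]] = SHOULDERS
        pair = coms_mm[two]
        sh_centroids = pair[np.argsort(pair[:, 0])]  # left (low x) first

    counts: dict[str, int] = {v: 0 for v in BONE_LABEL_NAMES.values()}
    for lbl, n in comps:
        code = assigned.get(lbl, OTHER)
        out[labels.data == lbl] = code
        counts[BONE_LABEL_NAMES[code]] += n
    return BoneSegmentation(out, vol.spacing_mm, vol.origin_mm.copy(), counts, sh_centroids)


def _neck_pivot_xy(front_xy, head_dir_xy, sh_xy, body_dir_xy, cran_xy):
    """Neck pivot in the horizontal plane.

    The bend is a rotation about a vertical axis, so the pivot is the
    intersection of the head and body axes projected to xy; for a straight
    pose (axes parallel) it falls midway between cranium and shoulders.  The
    result is clamped to lie on the body axis between the two.
    """
    h = head_dir_xy / np.linalg.norm(head_dir_xy)
    b = body_dir_xy / np.linalg.norm(body_dir_xy)
    cross = h[0] * b[1] - h[1] * b[0]
    if abs(cross) < 0.05:
        p = 0.5 * (cran_xy + sh_xy)
    else:
        w = sh_xy - front_xy
        t = (w[0] * b[1] - w[1] * b[0]) / cross
        p = front_xy + t * h
    lo = float((cran_xy - sh_xy) @ b)
    u = float(np.clip((p - sh_xy) @ b, lo + 0.5, -0.5))
    return sh_xy + u * b


def build_symmetry_chain(bone: BoneSegmentation, teeth: ToothLandmarks) -> SymmetryChain:
    """Four-node chain: snout, cranium center, neck pivot, shoulder midpoint.

    The neck pivot is the intersection of the head axis (front-to-back tooth
    line) and the body axis (through the shoulder midpoint, perpendicular to
    the shoulder pair); for a straight pose the axes are collinear and the
    pivot falls between cranium and shoulders.  Left/right points are taken
    from the shoulder centroids and the cranium's lateral extent and are
    symmetrized so paired distances from the midline are equal.
    """
    if bone.shoulder_centroids_mm is None:
        raise LandmarkError("shoulders not found; chain needs at least 3 nodes")
    sh_l, sh_r = bone.shoulder_centroids_mm
    sh_mid = 0.5 * (sh_l + sh_r)

    cran_idx = np.argwhere(bone.mask(CRANIUM))
    origin = bone.origin_mm
    s = bone.spacing_mm
    cran_mm = origin + (cran_idx + 0.5) * s
    cran_c = cran_mm.mean(axis=0)

    head_axis = teeth.back_mm - teeth.front_mm
    head_axis = head_axis / np.linalg.norm(head_axis)
    # head lateral direction: horizontal, perpendicular to the head axis
    lat_head = np.cross(head_axis, [0.0, 0.0, 1.0])
    lat_head = lat_head / np.linalg.norm(lat_head)
    half_w = float(np.abs((cran_mm - cran_c) @ lat_head).max())

    pair_vec = sh_r - sh_l
    body_axis = np.cross([0.0, 0.0, 1.0], pair_vec)
    body_axis = body_axis / np.linalg.norm(body_axis)
    if body_axis[1] < 0:
        body_axis = -body_axis  # point posterior

    pivot_xy = _neck_pivot_xy(
        teeth.front_mm[:2], head_axis[:2], sh_mid[:2], body_axis[:2], cran_c[:2]
    )
    pivot = np.array([pivot_xy[0], pivot_xy[1], 0.5 * (cran_c[2] + sh_mid[2])])

    half_sh = 0.5 * float(np.linalg.norm(pair_vec))
    lat_body = pair_vec / np.linalg.norm(pair_vec)

    def node(mid, lat, w, name):
        return ChainNode(np.asarray(mid, float), mid - lat * w, mid + lat * w, name)

    nodes = [
        node(teeth.front_mm, lat_head, 2.0, "snout"),
        node(cran_c, lat_head, half_w, "cranium"),
        node(pivot, lat_body, half_sh, "neck_pivot"),
        ChainNode(sh_mid, sh_l, sh_r, "shoulders"),
    ]
    # enforce anterior->posterior monotonicity of midline points
    keep = [nodes[0]]
    for n in nodes[1:]:
        if n.mid_mm[1] > keep[-1].mid_mm[1] + 0.5:
            keep.append(n)
    if len(keep) < 3:
        raise LandmarkError("fewer than 3 recoverable chain nodes")
    return SymmetryChain(keep)
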