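"""Synthetic CBCT phantoms with known ground truth.

Every downstream stage (splitting, anatomy, symmetry, tumor segmentation,
growth analytics) is exercised against volumes produced here.  A phantom
mouse is built from implicit solids on a calibrated four-class intensity
scale (air 0, acrylic 500, soft tissue 1000, bone 2500, teeth 4000 arbitrary
units — real scanners print no absolute values; every threshold in the
pipeline keys on the *ordering* of these classes):

* soft-tissue body and head ellipsoids,
* bone-class cranium and jaw shells plus a bilateral shoulder pair,
* three tooth clusters (front, bottom, back) on the head midline,
* an optional one-sided ellipsoidal cheek tumor of known volume,
* an acrylic bed plane / multi-mouse holder and nosecone tubes.

The head (cranium, jaw, teeth, tumor) can bend laterally about a neck pivot;
with no tumor the two head half-spaces are exact mirror images about the
bent midline surface, which is the property the symmetry-based tumor
detector exploits.  Gaussian intensity noise (default sigma = 5% of the
soft-tissue value) is added on top of the class image.

Water-tube standards and simulated caliper/CT growth datasets with
switchable measurer-bias effects are also generated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import GrowthCurve, GrowthParams, eval_growth_model
from .voxcore import ScanVolume

__all__ = [
    "AIR",
    "ACRYLIC",
    "SOFT_TISSUE",
    "BONE",
    "TOOTH",
    "WATER",
    "DEFAULT_NOISE_SIGMA",
    "TumorSpec",
    "MouseSpec",
    "MouseTruth",
    "PhantomTruth",
    "GrowthDataset",
    "make_mouse_phantom",
    "make_multimouse_scan",
    "make_water_tubes",
    "make_growth_dataset",
]

# Calibrated intensity classes (arbitrary units).
AIR = 0.0
ACRYLIC = 500.0
SOFT_TISSUE = 1000.0
BONE = 2500.0
TOOTH = 4000.0
WATER = 1000.0
DEFAULT_NOISE_SIGMA = 50.0  # 5% of soft tissue

# ---------------------------------------------------------------------------
# Mouse geometry (local frame: origin at head center, x lateral, y
# anterior->posterior with the snout at negative y, z up; units mm)
# ---------------------------------------------------------------------------

HEAD_CENTER = np.zeros(3)
HEAD_SEMI = np.array([4.5, 6.0, 4.0])
BODY_CENTER = np.array([0.0, 9.5, -0.5])
BODY_SEMI = np.array([5.5, 11.5, 4.5])
CRANIUM_CENTER = np.array([0.0, 0.8, 1.6])
CRANIUM_SEMI = np.array([3.4, 4.2, 2.2])
CRANIUM_INNER = 0.72  # shell = outer minus inner*outer
JAW_CENTER = np.array([0.0, -2.6, -2.5])
JAW_SEMI = np.array([2.6, 2.8, 1.1])
JAW_INNER = 0.65
SHOULDER_Y, SHOULDER_X, SHOULDER_Z, SHOULDER_R = 8.0, 4.2, 0.8, 1.7
TOOTH_R = 0.8
TOOTH_FRONT = np.array([0.0, -5.2, -0.6])
TOOTH_BOTTOM = np.array([0.0, -3.2, -2.6])
TOOTH_BACK = np.array([0.0, -0.6, -1.6])
NECK_PIVOT = np.array([0.0, 5.0, 0.0])
BODY_BOTTOM_Z = BODY_CENTER[2] - BODY_SEMI[2]  # where the mouse rests on a bed


@dataclass
class TumorSpec:
    """One-sided ellipsoidal cheek tumor, positioned in the head frame.

    ``center_mm`` is relative to the head center, with a positive lateral
    component; ``side`` flips its sign.  Semi-axes are (lateral, AP,
    vertical).
    """

    center_mm: np.ndarray
    semi_axes_mm: np.ndarray
    side: str = "right"
    intensity: float = SOFT_TISSUE

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.semi_axes_mm = np.asarray(self.semi_axes_mm, dtype=float)
        if np.any(self.semi_axes_mm <= 0):
            raise ValueError("tumor semi-axes must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def analytic_volume_mm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes_mm))

    @property
    def signed_center_mm(self) -> np.ndarray:
        c = self.center_mm.copy()
        c[0] = abs(c[0]) if self.side == "right" else -abs(c[0])
        return c

    @classmethod
    def from_volume(
        cls,
        volume_mm3: float,
        side: str = "right",
        aspect: tuple[float, float, float] = (1.0, 1.15, 0.85),
        embed_fraction: float = 0.25,
        center_y: float = -1.5,
        center_z: float = -0.3,
    ) -> "TumorSpec":
        """Tumor of a requested analytic volume attached to the cheek.

        The ellipsoid is placed just outside the head surface with an
        ``embed_fraction`` of its lateral semi-axis buried in the cheek so
        the excess over the mirrored contralateral side is (nearly) the full
        ellipsoid while the tumor stays connected to the body.
        """
        if volume_mm3 <= 0:
            raise ValueError("tumor volume must be positive")
        aspect = np.asarray(aspect, dtype=float)
        s = (3.0 * volume_mm3 / (4.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
        semi = aspect * s
        # head half-width at the tumor's (y, z)
        inside = 1.0 - (center_y / HEAD_SEMI[1]) ** 2 - (center_z / HEAD_SEMI[2]) ** 2
        half_width = HEAD_SEMI[0] * np.sqrt(max(inside, 0.0))
        cx = half_width + semi[0] * (1.0 - embed_fraction)
        return cls(np.array([cx, center_y, center_z]), semi, side=side)


@dataclass
class MouseSpec:
    """One slot of a multi-mouse scan."""

    mouse_id: str
    bend_deg: float = 0.0
    tumor: TumorSpec | None = None
    present: bool = True


@dataclass
class MouseTruth:
    mouse_id: str
    slot: int
    occupied: bool
    head_center_mm: np.ndarray
    bend_deg: float
    tumor_spec: TumorSpec | None
    tumor_mask: np.ndarray | None  # full-volume bool, excess over symmetric body
    tumor_volume_mm3: float  # voxelized excess (what mirror subtraction sees)
    tumor_analytic_mm3: float
    landmarks: dict[str, np.ndarray]
    tumor_solid_mm3: float = 0.0  # voxelized full ellipsoid incl. embedded cap
    x_range_mm: tuple[float, float] | None = None
    z_range_mm: tuple[float, float] | None = None


@dataclass
class PhantomTruth:
    layout: str
    spacing_mm: float
    noise_sigma: float
    mice: list[MouseTruth] = field(default_factory=list)
    bed: dict | None = None
    platform_heights_mm: list[float] = field(default_factory=list)
    foreign_masks: dict[str, np.ndarray] = field(default_factory=dict)
    water: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Implicit-solid helpers
# ---------------------------------------------------------------------------


def _ellipsoid(x, y, z, center, semi):
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _sphere(x, y, z, center, r):
    return _ellipsoid(x, y, z, center, (r, r, r))


def _head_frame(x, y, z, bend_deg):
    """Local coordinates pulled back through the neck rotation.

    The head is placed by rotating the straight geometry by ``bend_deg``
    about the vertical axis through the neck pivot; evaluating geometry at
    the inversely rotated coordinates paints the bent head.
    """
    if bend_deg == 0.0:
        return x, y, z
    th = np.deg2rad(bend_deg)
    c, s = np.cos(th), np.sin(th)
    dx = x - NECK_PIVOT[0]
    dy = y - NECK_PIVOT[1]
    qx = c * dx + s * dy + NECK_PIVOT[0]
    qy = -s * dx + c * dy + NECK_PIVOT[1]
    return qx, qy, z


def _rotate_head_point(q, bend_deg):
    """Map a straight-pose head-frame point to its bent-pose position."""
    th = np.deg2rad(bend_deg)
    c, s = np.cos(th), np.sin(th)
    d = np.asarray(q, dtype=float) - NECK_PIVOT
    return NECK_PIVOT + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1], d[2]])


def _paint_mouse(
    cls_arr: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    head_center: np.ndarray,
    bend_deg: float,
    tumor: TumorSpec | None,
    occupancy: np.ndarray,
) -> dict:
    """Paint one mouse into the class image; returns truth information."""
    if abs(bend_deg) > 30.0:
        raise ValueError("|neck bend| must be <= 30 degrees")
    shape = cls_arr.shape
    # local-frame bounding box
    lx, hx = -7.5, 7.5
    if tumor is not None:
        sc = tumor.signed_center_mm
        if tumor.side == "right":
            hx = max(hx, sc[0] + tumor.semi_axes_mm[0] + 1.0)
        else:
            lx = min(lx, sc[0] - tumor.semi_axes_mm[0] - 1.0)
    if bend_deg != 0.0:
        swing = 11.5 * abs(np.sin(np.deg2rad(bend_deg))) + 1.0
        lx -= swing
        hx += swing
    lo = np.array([lx, -9.0, BODY_BOTTOM_Z - 0.6])
    hi = np.array([hx, BODY_CENTER[1] + BODY_SEMI[1] + 1.0, 4.8])
    i0 = np.floor((head_center + lo - origin) / spacing - 0.5).astype(int)
    i1 = np.ceil((head_center + hi - origin) / spacing + 0.5).astype(int)
    if tumor is not None:
        t_world = head_center + _rotate_head_point(tumor.signed_center_mm, bend_deg)
        sx, sy, sz = tumor.semi_axes_mm
        ext = np.array([max(sx, sy), max(sx, sy), sz])  # xy bound covers rotation
        t_lo = t_world - ext - spacing
        t_hi = t_world + ext + spacing
        if np.any(t_lo < origin) or np.any(
            t_hi > origin + np.asarray(shape) * spacing
        ):
            raise ValueError("tumor extends outside the scan volume")
    i0c = np.maximum(i0, 0)
    i1c = np.minimum(i1, shape)
    sub = tuple(slice(a, b) for a, b in zip(i0c, i1c))

    ax = [
        origin[d] + (np.arange(i0c[d], i1c[d]) + 0.5) * spacing - head_center[d]
        for d in range(3)
    ]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    qx, qy, qz = _head_frame(x, y, z, bend_deg)

    soft = _ellipsoid(qx, qy, qz, HEAD_CENTER, HEAD_SEMI) | _ellipsoid(
        x, y, z, BODY_CENTER, BODY_SEMI
    )
    cran_o = _ellipsoid(qx, qy, qz, CRANIUM_CENTER, CRANIUM_SEMI)
    cran_i = _ellipsoid(qx, qy, qz, CRANIUM_CENTER, CRANIUM_SEMI * CRANIUM_INNER)
    jaw_o = _ellipsoid(qx, qy, qz, JAW_CENTER, JAW_SEMI)
    jaw_i = _ellipsoid(qx, qy, qz, JAW_CENTER, JAW_SEMI * JAW_INNER)
    sh_l = _sphere(x, y, z, (-SHOULDER_X, SHOULDER_Y, SHOULDER_Z), SHOULDER_R)
    sh_r = _sphere(x, y, z, (SHOULDER_X, SHOULDER_Y, SHOULDER_Z), SHOULDER_R)
    bone = (cran_o & ~cran_i) | (jaw_o & ~jaw_i) | sh_l | sh_r
    teeth = (
        _sphere(qx, qy, qz, TOOTH_FRONT, TOOTH_R)
        | _sphere(qx, qy, qz, TOOTH_BOTTOM, TOOTH_R)
        | _sphere(qx, qy, qz, TOOTH_BACK, TOOTH_R)
    )
    baseline = soft | bone | teeth

    tumor_solid = None
    if tumor is not None:
        tumor_solid = _ellipsoid(
            qx, qy, qz, tumor.signed_center_mm, tumor.semi_axes_mm
        )
    occupied = baseline if tumor_solid is None else (baseline | tumor_solid)

    if np.any(occupancy[sub] & occupied):
        raise ValueError("overlapping mice in multi-mouse phantom")

    view = cls_arr[sub]
    view[soft] = SOFT_TISSUE
    tumor_mask_sub = None
    if tumor_solid is not None:
        paintable = tumor_solid & ((view == AIR) | (view == SOFT_TISSUE))
        view[paintable] = tumor.intensity
        tumor_mask_sub = tumor_solid & ~baseline
    view[bone] = BONE
    view[teeth] = TOOTH
    occupancy[sub] |= occupied

    def world(q_head=None, p_body=None):
        if q_head is not None:
            return head_center + _rotate_head_point(q_head, bend_deg)
        return head_center + np.asarray(p_body, dtype=float)

    landmarks = {
        "front_tooth": world(q_head=TOOTH_FRONT),
        "bottom_tooth": world(q_head=TOOTH_BOTTOM),
        "back_tooth": world(q_head=TOOTH_BACK),
        "cranium_center": world(q_head=CRANIUM_CENTER),
        "shoulder_left": world(p_body=(-SHOULDER_X, SHOULDER_Y, SHOULDER_Z)),
        "shoulder_right": world(p_body=(SHOULDER_X, SHOULDER_Y, SHOULDER_Z)),
        "neck_pivot": world(p_body=NECK_PIVOT),
    }

    idx = np.nonzero(occupied)
    x_range = (
        float(head_center[0] + ax[0][idx[0].min()]),
        float(head_center[0] + ax[0][idx[0].max()]),
    )
    z_range = (
        float(head_center[2] + ax[2][idx[2].min()]),
        float(head_center[2] + ax[2][idx[2].max()]),
    )

    out = {
        "landmarks": landmarks,
        "x_range": x_range,
        "z_range": z_range,
        "tumor_mask_sub": tumor_mask_sub,
        "tumor_solid_voxels": 0 if tumor_solid is None else int(tumor_solid.sum()),
        "sub": sub,
    }
    return out


def _finish_mouse_truth(
    result: dict,
    shape,
    spacing: float,
    mouse_id: str,
    slot: int,
    head_center: np.ndarray,
    bend_deg: float,
    tumor: TumorSpec | None,
) -> MouseTruth:
    tumor_mask = None
    voxel_vol = 0.0
    analytic = 0.0
    if tumor is not None:
        tumor_mask = np.zeros(shape, dtype=bool)
        tumor_mask[result["sub"]] = result["tumor_mask_sub"]
        voxel_vol = float(tumor_mask.sum()) * spacing**3
        analytic = tumor.analytic_volume_mm3
    return MouseTruth(
        mouse_id=mouse_id,
        slot=slot,
        occupied=True,
        head_center_mm=np.asarray(head_center, dtype=float),
        bend_deg=bend_deg,
        tumor_spec=tumor,
        tumor_mask=tumor_mask,
        tumor_volume_mm3=voxel_vol,
        tumor_analytic_mm3=analytic,
        tumor_solid_mm3=result["tumor_solid_voxels"] * spacing**3,
        landmarks=result["landmarks"],
        x_range_mm=result["x_range"],
        z_range_mm=result["z_range"],
    )


# ---------------------------------------------------------------------------
# Single-mouse phantom
# ---------------------------------------------------------------------------


def make_mouse_phantom(
    seed: int = 0,
    bend_deg: float = 0.0,
    tumor: TumorSpec | None = None,
    spacing_mm: float = 0.4,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> tuple[ScanVolume, PhantomTruth]:
    """Single-mouse phantom without a bed.

    With ``tumor=None`` and ``bend_deg=0`` the class image equals its own
    x-mirror exactly (the lateral extent and voxel centers are symmetric
    about the head midline by construction); noise breaks this only
    stochastically.
    """
    if abs(bend_deg) > 30.0:
        raise ValueError("|neck bend| must be <= 30 degrees")
    s = float(spacing_mm)
    x_half = 8.5
    if tumor is not None:
        sc = tumor.signed_center_mm
        x_half = max(x_half, abs(sc[0]) + tumor.semi_axes_mm[0] + 2.0)
    if bend_deg != 0.0:
        x_half += 11.5 * abs(np.sin(np.deg2rad(bend_deg))) + 1.0
    nx = 2 * int(np.ceil(x_half / s))
    y_lo, y_hi = -9.5, 22.5
    z_lo, z_hi = -6.2, 5.2
    ny = int(np.ceil((y_hi - y_lo) / s))
    nz = int(np.ceil((z_hi - z_lo) / s))
    origin = np.array([-nx * s / 2.0, y_lo, z_lo])
    shape = (nx, ny, nz)

    cls = np.full(shape, AIR, dtype=np.float32)
    occupancy = np.zeros(shape, dtype=bool)
    head_center = np.zeros(3)
    res = _paint_mouse(cls, origin, s, head_center, bend_deg, tumor, occupancy)
    truth = PhantomTruth(layout="single", spacing_mm=s, noise_sigma=noise_sigma)
    truth.mice.append(
        _finish_mouse_truth(res, shape, s, "m1", 0, head_center, bend_deg, tumor)
    )

    data = cls.astype(np.float64)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, shape)
    return ScanVolume(data.astype(np.float32), s, origin), truth


# ---------------------------------------------------------------------------
# Multi-mouse scans
# ---------------------------------------------------------------------------


def _paint_slab(cls, origin, spacing, shape, x_lo, x_hi, y_lo, y_hi, z_lo, z_hi, value):
    """Paint an axis-aligned acrylic slab; returns its mask."""
    ax = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    m = (
        ((ax[0] >= x_lo) & (ax[0] <= x_hi))[:, None, None]
        & ((ax[1] >= y_lo) & (ax[1] <= y_hi))[None, :, None]
        & ((ax[2] >= z_lo) & (ax[2] <= z_hi))[None, None, :]
    )
    cls[m & (cls == AIR)] = value
    return m


def _paint_nosecone(cls, origin, spacing, shape, center_xz, y_lo, y_hi, r_out=3.5, wall=0.8):
    """Hollow acrylic cylinder along y in front of a snout; returns its mask."""
    ax = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    rx = (ax[0] - center_xz[0])[:, None, None]
    rz = (ax[2] - center_xz[1])[None, None, :]
    rad2 = rx**2 + rz**2
    in_y = ((ax[1] >= y_lo) & (ax[1] <= y_hi))[None, :, None]
    m = in_y & (rad2 <= r_out**2) & (rad2 >= (r_out - wall) ** 2)
    cls[m & (cls == AIR)] = ACRYLIC
    return m


def make_multimouse_scan(
    specs: list[MouseSpec],
    layout: str,
    spacing_mm: float = 0.4,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    jitter_mm: float = 0.0,
    jitter_bend_deg: float = 0.0,
    nosecones: bool = False,
    pitch_mm: float | None = None,
    bed_tilt_deg: tuple[float, float] = (0.0, 0.0),
) -> tuple[ScanVolume, PhantomTruth]:
    """Multi-mouse phantom scan.

    ``three_row``: three mice side by side along x on one acrylic bed plane.
    ``five_holder``: three mice on a top platform over two mice on two
    slightly different bottom-platform heights (three distinct heights in
    total).  ``bed_tilt_deg`` tilts the three-row bed (about y, about x).
    """
    rng = np.random.default_rng(seed)
    s = float(spacing_mm)
    if layout == "three_row":
        if len(specs) != 3:
            raise ValueError("three_row layout requires exactly 3 mouse specs")
        pitch = 28.0 if pitch_mm is None else float(pitch_mm)
        slot_x = np.array([-pitch, 0.0, pitch])
        tum_ext = 0.0
        for sp in specs:
            if sp.present and sp.tumor is not None:
                sc = sp.tumor.signed_center_mm
                tum_ext = max(tum_ext, abs(sc[0]) + sp.tumor.semi_axes_mm[0] - 7.0)
        x_half = pitch + 9.5 + tum_ext + jitter_mm
        y_lo, y_hi = -11.0, 23.0
        z_lo, z_hi = -8.5, 5.5
        nx = 2 * int(np.ceil(x_half / s))
        ny = int(np.ceil((y_hi - y_lo) / s))
        nz = int(np.ceil((z_hi - z_lo) / s))
        origin = np.array([-nx * s / 2.0, y_lo, z_lo])
        shape = (nx, ny, nz)
        cls = np.full(shape, AIR, dtype=np.float32)
        occupancy = np.zeros(shape, dtype=bool)
        truth = PhantomTruth(layout=layout, spacing_mm=s, noise_sigma=noise_sigma)

        # tilted bed: mice rest on the local bed height
        tx, ty = np.deg2rad(bed_tilt_deg[0]), np.deg2rad(bed_tilt_deg[1])
        px, py = np.tan(tx), np.tan(ty)
        bed_top0 = -5.6

        def bed_top(xv, yv):
            return bed_top0 + px * xv + py * yv

        # paint bed as a (possibly tilted) slab of acrylic
        ax = [origin[d] + (np.arange(shape[d]) + 0.5) * s for d in range(3)]
        surf = bed_top(ax[0][:, None, None], ax[1][None, :, None])
        bed_mask = (ax[2][None, None, :] <= surf) & (
            ax[2][None, None, :] >= surf - 1.2
        )
        cls[bed_mask] = ACRYLIC
        truth.bed = {"top_z_mm": bed_top0, "slope_x": px, "slope_y": py}
        truth.platform_heights_mm = [bed_top0]

        for slot, sp in enumerate(specs):
            if not sp.present:
                truth.mice.append(
                    MouseTruth(
                        sp.mouse_id, slot, False, np.array([slot_x[slot], 0.0, 0.0]),
                        0.0, None, None, 0.0, 0.0, {},
                    )
                )
                continue
            jx = rng.uniform(-jitter_mm, jitter_mm) if jitter_mm else 0.0
            jy = rng.uniform(-jitter_mm, jitter_mm) if jitter_mm else 0.0
            jb = rng.uniform(-jitter_bend_deg, jitter_bend_deg) if jitter_bend_deg else 0.0
            xc = slot_x[slot] + jx
            zc = bed_top(xc, 0.0) - BODY_BOTTOM_Z  # body rests on the bed
            head_center = np.array([xc, jy, zc])
            bend = sp.bend_deg + jb
            res = _paint_mouse(cls, origin, s, head_center, bend, sp.tumor, occupancy)
            truth.mice.append(
                _finish_mouse_truth(
                    res, shape, s, sp.mouse_id, slot, head_center, bend, sp.tumor
                )
            )
            if nosecones:
                snout_y = head_center[1] - HEAD_SEMI[1]
                m = _paint_nosecone(
                    cls, origin, s, shape, (xc, zc), snout_y - 7.0, snout_y - 1.0
                )
                truth.foreign_masks[f"nosecone_slot{slot}"] = m

    elif layout == "five_holder":
        if len(specs) != 5:
            raise ValueError("five_holder layout requires exactly 5 mouse specs")
        pitch = 15.0 if pitch_mm is None else float(pitch_mm)
        top_platform = 6.5
        bot_tops = (-5.6, -6.6)  # two bottom platform heights
        # slots: 0-2 top row (x = -pitch, 0, pitch), 3 bottom x<0, 4 bottom x>0
        slot_xz = [
            (-pitch, top_platform - BODY_BOTTOM_Z),
            (0.0, top_platform - BODY_BOTTOM_Z),
            (pitch, top_platform - BODY_BOTTOM_Z),
            (-9.0, bot_tops[0] - BODY_BOTTOM_Z),
            (9.0, bot_tops[1] - BODY_BOTTOM_Z),
        ]
        x_half = pitch + 9.0 + jitter_mm
        y_lo, y_hi = -11.0, 23.0
        z_lo, z_hi = -9.5, top_platform - BODY_BOTTOM_Z + 5.5
        nx = 2 * int(np.ceil(x_half / s))
        ny = int(np.ceil((y_hi - y_lo) / s))
        nz = int(np.ceil((z_hi - z_lo) / s))
        origin = np.array([-nx * s / 2.0, y_lo, z_lo])
        shape = (nx, ny, nz)
        cls = np.full(shape, AIR, dtype=np.float32)
        occupancy = np.zeros(shape, dtype=bool)
        truth = PhantomTruth(layout=layout, spacing_mm=s, noise_sigma=noise_sigma)
        xmin, xmax = origin[0], origin[0] + nx * s
        _paint_slab(cls, origin, s, shape, xmin, xmax, y_lo, y_hi,
                    top_platform - 1.2, top_platform, ACRYLIC)
        _paint_slab(cls, origin, s, shape, 0.0, xmax, y_lo, y_hi,
                    bot_tops[1] - 1.2, bot_tops[1], ACRYLIC)
        _paint_slab(cls, origin, s, shape, xmin, 0.0, y_lo, y_hi,
                    bot_tops[0] - 1.2, bot_tops[0], ACRYLIC)
        truth.platform_heights_mm = [top_platform, bot_tops[0], bot_tops[1]]

        for slot, sp in enumerate(specs):
            if not sp.present:
                truth.mice.append(
                    MouseTruth(
                        sp.mouse_id, slot, False,
                        np.array([slot_xz[slot][0], 0.0, slot_xz[slot][1]]),
                        0.0, None, None, 0.0, 0.0, {},
                    )
                )
                continue
            jx = rng.uniform(-jitter_mm, jitter_mm) if jitter_mm else 0.0
            jy = rng.uniform(-jitter_mm, jitter_mm) if jitter_mm else 0.0
            jb = rng.uniform(-jitter_bend_deg, jitter_bend_deg) if jitter_bend_deg else 0.0
            head_center = np.array([slot_xz[slot][0] + jx, jy, slot_xz[slot][1]])
            bend = sp.bend_deg + jb
            res = _paint_mouse(cls, origin, s, head_center, bend, sp.tumor, occupancy)
            truth.mice.append(
                _finish_mouse_truth(
                    res, shape, s, sp.mouse_id, slot, head_center, bend, sp.tumor
                )
            )
    else:
        raise ValueError(f"unknown layout {layout!r}")

    data = cls.astype(np.float64)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, shape)
    return ScanVolume(data.astype(np.float32), s, origin), truth


# ---------------------------------------------------------------------------
# Water-tube standards
# ---------------------------------------------------------------------------


def make_water_tubes(
    volumes_ul: list[float],
    spacing_mm: float = 0.2,
    seed: int = 0,
    noise_sigma: float = 25.0,
    inner_radius_mm: float = 3.0,
    wall_mm: float = 0.8,
) -> tuple[ScanVolume, PhantomTruth]:
    """Plastic tubes holding known water volumes (1 ul = 1 mm^3).

    Tube walls are acrylic class (below water intensity); water columns are
    filled to the requested volume to within one voxel (the top slice is
    partially filled from the tube axis outward, a discrete meniscus), so
    voxel counting recovers the requested volumes up to class-noise effects.
    """
    s = float(spacing_mm)
    r_in, wall = float(inner_radius_mm), float(wall_mm)
    r_out = r_in + wall
    n_tubes = len(volumes_ul)
    pitch = 2 * r_out + 3.0
    x_half = (n_tubes * pitch) / 2.0 + 2.0
    max_h = max([v / (np.pi * r_in**2) for v in volumes_ul] + [5.0])
    z_top = 2.0 + max_h + 4.0
    nx = int(np.ceil(2 * x_half / s))
    ny = int(np.ceil(2 * (r_out + 2.0) / s))
    nz = int(np.ceil((z_top + 1.0) / s))
    origin = np.array([-x_half, -(r_out + 2.0), 0.0])
    shape = (nx, ny, nz)
    cls = np.full(shape, AIR, dtype=np.float32)
    truth = PhantomTruth(layout="water_tubes", spacing_mm=s, noise_sigma=noise_sigma)

    ax = [origin[d] + (np.arange(shape[d]) + 0.5) * s for d in range(3)]
    voxel_vol = s**3
    for t, v_ul in enumerate(volumes_ul):
        xc = -x_half + (t + 0.5) * pitch + 1.0
        rx = (ax[0] - xc)[:, None]
        ry = ax[1][None, :]
        rad2 = rx**2 + ry**2  # (nx, ny)
        wall_xy = (rad2 <= r_out**2) & (rad2 > r_in**2)
        in_xy = rad2 <= r_in**2
        z_in = (ax[2] >= 1.0) & (ax[2] <= z_top - 2.0)
        cap = (ax[2] >= 1.0) & (ax[2] <= 2.0)
        cls[wall_xy[:, :, None] & z_in[None, None, :]] = ACRYLIC
        cls[in_xy[:, :, None] & cap[None, None, :]] = ACRYLIC

        target_n = int(round(float(v_ul) / voxel_vol))
        water_count = 0
        if target_n > 0:
            ii, jj = np.nonzero(in_xy)
            order = np.lexsort((jj, ii, rad2[ii, jj]))
            ii, jj = ii[order], jj[order]
            per_slice = len(ii)
            k0 = int(np.searchsorted(ax[2], 2.0 + s / 2.0))
            n_full = target_n // per_slice
            rem = target_n - n_full * per_slice
            for k in range(k0, k0 + n_full):
                cls[in_xy, k] = WATER
            if rem:
                cls[ii[:rem], jj[:rem], k0 + n_full] = WATER
            water_count = n_full * per_slice + rem
        truth.water.append(
            {
                "requested_ul": float(v_ul),
                "center_x_mm": xc,
                "water_voxels": water_count,
                "water_volume_mm3": water_count * voxel_vol,
            }
        )

    data = cls.astype(np.float64)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, shape)
    return ScanVolume(data.astype(np.float32), s, origin), truth


# ---------------------------------------------------------------------------
# Simulated growth datasets
# ---------------------------------------------------------------------------


@dataclass
class GrowthDataset:
    caliper: list[GrowthCurve]
    ct: list[GrowthCurve]
    truth: list[GrowthParams]
    rt_day: float
    schedule: np.ndarray


def sample_growth_params(rng: np.random.Generator, rt_day: float = 8.0) -> GrowthParams:
    """Plausible post-radiotherapy growth parameters for one tumor.

    The constant is tied to the logistic amplitude (``h = -d``) so the curve
    starts near zero and plateaus at ``d`` under the as-printed model form.
    """
    a = float(rng.lognormal(np.log(60.0), 0.4))
    b = rt_day + float(rng.uniform(1.0, 4.0))
    c = float(rng.uniform(4.0, 9.0))
    d = float(rng.uniform(150.0, 500.0))
    # aggressive head-and-neck lines regrow with doubling times under ~4
    # days, i.e. fractional rates of 0.15-0.5 per day
    f = float(rng.uniform(0.15, 0.5))
    g = float(rng.uniform(18.0, 34.0))
    return GrowthParams(a, b, c, d, f, g, -d)


def make_growth_dataset(
    n_mice: int = 20,
    true_params: list[GrowthParams] | None = None,
    noise_sigma: float = 0.1,
    schedule: np.ndarray | None = None,
    seed: int = 0,
    rt_day: float = 8.0,
    floor_mm3: float = 0.0,
    contextual_bias: float = 0.0,
    smoothing_weight: float = 0.0,
    nonregrow_fraction: float = 0.25,
) -> GrowthDataset:
    """Paired caliper/CT growth curves from the growth model plus noise.

    CT curves are the model plus multiplicative noise.  A
    ``nonregrow_fraction`` of sampled mice are durably controlled by the
    radiotherapy (logistic amplitude zero), as in real treated cohorts where
    a fraction of tumors never regrow.  Caliper curves add three
    independently switchable measurer-bias effects: a reporting floor for
    small tumors (``floor_mm3``), a contextual bias that inflates
    small-tumor readings in proportion to the cohort's daily mean CT volume
    (``contextual_bias``; small means below the daily cohort mean), and
    smoothing toward the previously recorded value (``smoothing_weight`` in
    [0, 1)).  With ``noise_sigma=0`` and all biases off, caliper == CT ==
    model.
    """
    rng = np.random.default_rng(seed)
    # every 4 days from day 4 to day 60 (15 timepoints): tumors regrow to
    # their plateau within the observation window, as in a full experiment
    days = np.arange(4.0, 61.0, 4.0) if schedule is None else np.asarray(schedule, float)
    if true_params is None:
        true_params = []
        for _ in range(n_mice):
            p = sample_growth_params(rng, rt_day)
            if rng.random() < nonregrow_fraction:
                p = GrowthParams(p.a, p.b, p.c, 0.0, p.f, p.g, 0.0)
            true_params.append(p)
    else:
        n_mice = len(true_params)
        for p in true_params:
            if p.c <= 0 or p.f < 0:
                raise ValueError("require c > 0 and f >= 0")

    clean = np.array([eval_growth_model(p, days) for p in true_params])
    ct = np.maximum(clean * (1.0 + rng.normal(0.0, noise_sigma, clean.shape)), 0.0)
    cal = np.maximum(clean * (1.0 + rng.normal(0.0, noise_sigma, clean.shape)), 0.0)

    if smoothing_weight > 0.0:
        w = float(smoothing_weight)
        sm = cal.copy()
        for j in range(1, cal.shape[1]):
            sm[:, j] = (1.0 - w) * cal[:, j] + w * sm[:, j - 1]
        cal = sm
    if contextual_bias > 0.0:
        cohort_mean = ct.mean(axis=0)
        small = clean < cohort_mean[None, :]
        cal = cal + contextual_bias * cohort_mean[None, :] * small
    if floor_mm3 > 0.0:
        cal = np.maximum(cal, floor_mm3)
    cal = np.maximum(cal, 0.0)

    cal_curves = [
        GrowthCurve(f"m{i + 1:03d}", "caliper", days, cal[i]) for i in range(n_mice)
    ]
    ct_curves = [
        GrowthCurve(f"m{i + 1:03d}", "ct", days, ct[i]) for i in range(n_mice)
    ]
    return GrowthDataset(cal_curves, ct_curves, list(true_params), rt_day, days)
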