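"""Turn one multi-mouse CBCT scan into cleaned single-mouse volumes.

Stages: intensity calibration against the air and soft-tissue histogram
modes, acrylic bed-plane detection and removal, horizontal (and, for the
five-mouse holder, vertical) splitting, removal of foreign objects and
neighbor limbs, and empty-slot detection.

Two redundant splitting signals are used for a row of mice: the mean
intensity of each sagittal (YZ) plane, whose interior local minima mark the
gaps between mice, and — as a fallback when that yields the wrong count —
the tooth-density voxel count per sagittal plane, whose local maxima mark
the mouse centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from . import phantom as _ph
from .voxcore import BinaryMask, ScanVolume, connected_components, threshold_mask

__all__ = [
    "CalibrationError",
    "BedDetectionError",
    "SplitError",
    "BedPlane",
    "SplitResult",
    "calibrate_intensity",
    "detect_bed_plane",
    "split_multimouse",
    "clean_single_mouse",
]


class CalibrationError(RuntimeError):
    pass


class BedDetectionError(RuntimeError):
    pass


class SplitError(RuntimeError):
    pass


# thresholds on the calibrated class scale
TISSUE_LOW = 0.5 * (_ph.ACRYLIC + _ph.SOFT_TISSUE)  # tissue-or-denser
TOOTH_LOW = 0.85 * _ph.TOOTH
OCCUPANCY_MM3 = 1000.0  # 1 cm^3 of tissue marks an occupied slot
BED_COLUMN_CUTOFF = 0.5 * (_ph.AIR + _ph.SOFT_TISSUE)


@dataclass
class BedPlane:
    """Bed surface z = p*x + q*y + r in voxel coordinates."""

    p: float
    q: float
    r: float
    points: np.ndarray  # (N, 3) inlier column bed points, voxel coords
    rms_vox: float

    def z_at(self, x, y):
        return self.p * np.asarray(x) + self.q * np.asarray(y) + self.r


@dataclass
class SplitResult:
    volumes: list[ScanVolume]
    occupied: list[bool | None]
    split_coords: dict
    log: dict = field(default_factory=dict)


def _smooth(sig: np.ndarray, width_vox: int) -> np.ndarray:
    w = max(int(width_vox) | 1, 1)  # odd
    kernel = np.ones(w) / w
    return np.convolve(sig, kernel, mode="same")


def calibrate_intensity(vol: ScanVolume, n_bins: int = 512) -> ScanVolume:
    """Affine intensity calibration from the air and soft-tissue modes.

    The two most massive histogram modes are mapped to the standard air (0)
    and soft-tissue values; the map is order-preserving.  A volume without a
    bimodal air/tissue histogram cannot be calibrated.
    """
    data = vol.data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise CalibrationError("constant-intensity volume")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(counts.astype(float), 3.0)
    peaks, props = signal.find_peaks(smooth, prominence=0.01 * smooth.max())
    if len(peaks) < 2:
        raise CalibrationError("histogram is not bimodal (air + soft tissue)")
    # two peaks holding the most mass = air and soft tissue
    order = np.argsort(props["prominences"])[::-1][:2]
    two = np.sort(peaks[order])
    air_mode, soft_mode = centers[two[0]], centers[two[1]]
    if soft_mode <= air_mode:
        raise CalibrationError("degenerate histogram modes")
    gain = _ph.SOFT_TISSUE / (soft_mode - air_mode)
    out = (data - air_mode) * gain
    return ScanVolume(out.astype(np.float32), vol.spacing_mm, vol.origin_mm.copy())


def detect_bed_plane(
    vol: ScanVolume,
    n_columns: int = 100,
    column_cutoff: float = BED_COLUMN_CUTOFF,
    z_hint: tuple[int, int] | None = None,
) -> BedPlane:
    """Find the acrylic bed plane below the mice.

    Means of ~``n_columns`` evenly spaced (x, y) voxel columns select the
    columns where no mouse rests (column mean below the air/soft-tissue
    midpoint); along each, the bed point is the z of the largest one-step
    intensity difference.  A least-squares plane is fitted through the bed
    points with one outlier-trimming pass (columns that clipped a mouse
    surface instead of the bed are rejected).  ``z_hint`` restricts the
    search to a z index range.
    """
    nx, ny, nz = vol.shape
    side = max(int(round(np.sqrt(n_columns))), 2)
    xs = np.linspace(nx * 0.05, nx * 0.95, side).astype(int)
    ys = np.linspace(ny * 0.05, ny * 0.95, side).astype(int)
    zlo, zhi = (0, nz) if z_hint is None else z_hint
    pts = []
    for xi in xs:
        for yi in ys:
            col = vol.data[xi, yi, zlo:zhi].astype(np.float64)
            if col.mean() >= column_cutoff:
                continue
            # acrylic-sized descending step (material below, air above);
            # the lowest such edge is the bed surface
            d = col[:-1] - col[1:]
            cand = np.flatnonzero((d >= 0.5 * _ph.ACRYLIC) & (d <= 1.52 * _ph.ACRYLIC))
            if len(cand) == 0:
                continue
            pts.append((float(xi), float(yi), float(zlo + cand[0] + 0.5)))
    pts = np.asarray(pts)
    if len(pts) < 3:
        raise BedDetectionError("fewer than 3 usable bed columns")

    def fit(p):
        A = np.column_stack([p[:, 0], p[:, 1], np.ones(len(p))])
        coef, *_ = np.linalg.lstsq(A, p[:, 2], rcond=None)
        resid = p[:, 2] - A @ coef
        return coef, resid

    # columns that clipped a mouse edge put their point on the mouse surface,
    # far from the bed: prefilter around the median height, then trim.
    dz = pts[:, 2] - np.median(pts[:, 2])
    mad = np.median(np.abs(dz - np.median(dz)))
    keep = np.abs(dz) < max(3.0, 3.0 * 1.4826 * mad)
    if keep.sum() >= 3:
        pts = pts[keep]
    coef, resid = fit(pts)
    for _ in range(2):
        keep = np.abs(resid) < max(1.5, 3.0 * np.std(resid))
        if keep.sum() < 3:
            break
        pts = pts[keep]
        coef, resid = fit(pts)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > 2.0:
        raise BedDetectionError(f"no consistent bed plane (residual {rms:.1f} vox)")
    return BedPlane(float(coef[0]), float(coef[1]), float(coef[2]), pts, rms)


def _remove_below_plane(vol: ScanVolume, plane: BedPlane, margin_vox: float = 1.5) -> None:
    nx, ny, nz = vol.shape
    zz = np.arange(nz)[None, None, :]
    surf = plane.z_at(
        np.arange(nx)[:, None, None], np.arange(ny)[None, :, None]
    )
    vol.data[zz <= surf + margin_vox] = _ph.AIR


def _row_splits_from_signals(
    vol: ScanVolume, expected_n: int, x_slice: slice, z_slice: slice, log: dict
) -> list[int]:
    """Split x-indices for a row of mice via the two redundant 1-D signals."""
    s = vol.spacing_mm
    width = int(round(5.0 / s))
    sub = vol.data[x_slice, :, z_slice]
    x0 = x_slice.start or 0

    sig_a = _smooth(sub.mean(axis=(1, 2)), width)
    prom_a = 0.1 * (sig_a.max() - sig_a.min())
    minima, _ = signal.find_peaks(-sig_a, prominence=prom_a)
    # an air gap is a broad flat valley: recenter each minimum on it
    minima = [_recenter_minimum(sig_a, m, 0.05 * prom_a) for m in minima]
    log["signal_a"] = sig_a
    log["signal_a_minima"] = np.asarray(minima) + x0
    if len(minima) == expected_n - 1:
        return [int(m) + x0 for m in minima]

    tooth = (sub >= TOOTH_LOW).sum(axis=(1, 2)).astype(float)
    sig_b = _smooth(tooth, width)
    prom_b = 0.1 * max(sig_b.max() - sig_b.min(), 1.0)
    maxima, _ = signal.find_peaks(sig_b, prominence=prom_b)
    log["signal_b"] = sig_b
    log["signal_b_maxima"] = maxima + x0
    if len(maxima) == expected_n:
        mids = [(maxima[i] + maxima[i + 1]) // 2 for i in range(expected_n - 1)]
        return [int(m) + x0 for m in mids]
    raise SplitError(
        f"could not split row: signal A gave {len(minima)} minima, "
        f"signal B gave {len(maxima)} maxima (expected {expected_n} mice); "
        "signals logged"
    )


def _recenter_minimum(sig: np.ndarray, m: int, tol: float) -> int:
    """Midpoint of the contiguous near-minimum valley around index ``m``."""
    level = sig[m] + tol
    lo = m
    while lo > 0 and sig[lo - 1] <= level:
        lo -= 1
    hi = m
    while hi < len(sig) - 1 and sig[hi + 1] <= level:
        hi += 1
    return (lo + hi) // 2


def _subvolume(vol: ScanVolume, x_slice: slice, z_slice: slice | None = None) -> ScanVolume:
    z_slice = z_slice or slice(None)
    data = vol.data[x_slice, :, z_slice].copy()
    origin = vol.origin_mm.copy()
    origin[0] += (x_slice.start or 0) * vol.spacing_mm
    if z_slice.start:
        origin[2] += z_slice.start * vol.spacing_mm
    return ScanVolume(data, vol.spacing_mm, origin)


def split_multimouse(vol: ScanVolume, layout: str, expected_n: int) -> SplitResult:
    """Split a calibrated multi-mouse scan into per-slot sub-volumes.

    ``three_row``: bed plane removed, then split along x.  ``five_holder``:
    platform heights are clustered from bed points into three groups; the
    scan is split in z between the top platform and the lower rows, the top
    row is split along x like a three-mouse row, and the bottom row is split
    at the x midline.
    """
    log: dict = {}
    vol = vol.copy()
    if layout == "three_row":
        if expected_n > 3:
            raise ValueError("three_row holds at most 3 mice")
        plane = detect_bed_plane(vol)
        log["bed_plane"] = (plane.p, plane.q, plane.r)
        _remove_below_plane(vol, plane)
        splits = _row_splits_from_signals(vol, expected_n, slice(None), slice(None), log)
        bounds = [0, *splits, vol.shape[0]]
        vols = [
            _subvolume(vol, slice(bounds[i], bounds[i + 1]))
            for i in range(expected_n)
        ]
        return SplitResult(vols, [None] * expected_n, {"x_splits": splits}, log)

    if layout == "five_holder":
        if expected_n != 5:
            raise ValueError("five_holder holds exactly 5 mice")
        plane_pts = _five_holder_platforms(vol, log)
        top_z = plane_pts["top_platform_z"]
        s = vol.spacing_mm
        z_top_start = int(np.ceil(top_z + 0.5))
        z_bot_end = int(np.floor(top_z - 1.6 / s))
        if z_top_start >= vol.shape[2] or z_bot_end <= 0:
            raise SplitError("five-holder platform clustering failed; log attached")
        top_slice = slice(z_top_start, vol.shape[2])
        bot_slice = slice(0, z_bot_end)
        top_splits = _row_splits_from_signals(vol, 3, slice(None), top_slice, log)
        bounds = [0, *top_splits, vol.shape[0]]
        x_mid = vol.shape[0] // 2
        vols = [
            _subvolume(vol, slice(bounds[0], bounds[1]), top_slice),
            _subvolume(vol, slice(bounds[1], bounds[2]), top_slice),
            _subvolume(vol, slice(bounds[2], bounds[3]), top_slice),
            _subvolume(vol, slice(0, x_mid), bot_slice),
            _subvolume(vol, slice(x_mid, vol.shape[0]), bot_slice),
        ]
        coords = {
            "z_split": z_top_start,
            "top_x_splits": top_splits,
            "bottom_x_split": x_mid,
        }
        return SplitResult(vols, [None] * 5, coords, log)

    raise ValueError(f"unknown layout {layout!r}")


def _five_holder_platforms(vol: ScanVolume, log: dict) -> dict:
    """Cluster per-column bed points into three platform heights."""
    nx, ny, nz = vol.shape
    side = 12
    xs = np.linspace(nx * 0.05, nx * 0.95, side).astype(int)
    ys = np.linspace(ny * 0.05, ny * 0.95, side).astype(int)
    zs = []
    for xi in xs:
        for yi in ys:
            col = vol.data[xi, yi, :].astype(np.float64)
            if col.mean() >= BED_COLUMN_CUTOFF:
                continue
            # every acrylic-sized descending edge (platform top surfaces);
            # tissue->air edges are about twice as large and are excluded
            d = col[:-1] - col[1:]
            edges = np.flatnonzero(
                (d >= 0.5 * _ph.ACRYLIC) & (d <= 1.52 * _ph.ACRYLIC)
            )
            zs.extend(float(e) + 0.5 for e in edges)
    if len(zs) < 6:
        raise SplitError("too few platform points in five-holder scan")
    zs = np.sort(np.asarray(zs))
    gaps = np.diff(zs)
    # three clusters = split at the two largest gaps (> 2 voxels)
    big = np.argsort(gaps)[::-1]
    cuts = sorted(int(b) for b in big[:2] if gaps[b] > 2.0)
    groups = np.split(zs, [c + 1 for c in cuts])
    heights = sorted(float(np.median(g)) for g in groups if len(g) >= 2)
    log["platform_heights_vox"] = heights
    if not heights:
        raise SplitError("platform clustering failed")
    return {"top_platform_z": heights[-1], "heights": heights}


def clean_single_mouse(
    vol: ScanVolume, layout: str = "three_row"
) -> tuple[ScanVolume, bool]:
    """Remove everything but the mouse from a split sub-volume.

    The slot is empty when the tissue-or-denser voxel count falls below a
    1 cm^3 equivalent.  Otherwise the largest connected component of the
    tissue mask is kept as the mouse and every other voxel — neighbor limbs,
    nosecone, holder walls, residual bed — is set to the air value.
    """
    tissue = threshold_mask(vol, TISSUE_LOW, np.inf)
    occ_vox = OCCUPANCY_MM3 / vol.voxel_volume_mm3
    if tissue.voxel_count() < occ_vox:
        return vol.copy(), False
    labels = connected_components(tissue, connectivity=26)
    keep = labels.component(labels.largest_label())
    out = np.where(keep, vol.data, np.float32(_ph.AIR))
    return ScanVolume(out, vol.spacing_mm, vol.origin_mm.copy()), True
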