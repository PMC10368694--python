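"""Spreadsheet-driven orchestration of the full analysis pipeline.

One task row describes one multi-mouse scan: path, layout, expected mouse
count, per-slot mouse IDs, scan date.  Each scan is calibrated, split into
single-mouse volumes, cleaned, and every occupied slot is pushed through the
head-segmentation chain (teeth -> bone -> symmetry chain -> curvilinear grid
-> mirror refinement -> excess height map -> tumor segmentation -> shape
metrics).  A failing mouse or scan never aborts the batch: failures are
logged and exported with a status column.

Execution is single-process and sequential; results are deterministic for
fixed inputs.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .anatomy import build_symmetry_chain, segment_bone, segment_teeth
from .scan_split import calibrate_intensity, clean_single_mouse, split_multimouse
from .symmetry import build_grid, refine_grid, resample_head
from .tumorseg import (
    backproject_tumor,
    excess_height_map,
    filter_height_map,
    shape_eigen,
    sphericalness,
    tumor_location,
)
from .voxcore import ScanVolume

__all__ = ["SegmentationConfig", "MouseResult", "segment_mouse", "run_tasks", "export_results"]

LAYOUT_CAPACITY = {"three_row": 3, "five_holder": 5, "single": 1}

RESULT_COLUMNS = [
    "mouse_id",
    "date",
    "volume_mm3",
    "e1",
    "e2",
    "e3",
    "sphericalness",
    "loc_lateral_mm",
    "loc_ap_mm",
    "loc_vertical_mm",
    "status",
]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the single-mouse segmentation chain."""

    tumor_side: str = "right"
    refine_steps: int = 10
    lambda_curv: float = 0.1
    max_disp_mm: float | None = None  # None -> one lattice voxel
    min_thickness_mm: float = 0.4
    smooth_mm: float = 0.3
    lateral_halfwidth_mm: float = 14.0
    standard_shape: tuple[int, int, int] | None = None

    @classmethod
    def from_yaml(cls, path) -> "SegmentationConfig":
        """Load configuration overrides from a YAML file."""
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "standard_shape" in doc and doc["standard_shape"] is not None:
            doc["standard_shape"] = tuple(doc["standard_shape"])
        return cls(**doc)


@dataclass
class MouseResult:
    mouse_id: str
    date: str = ""
    status: str = "ok"
    error: str = ""
    volume_mm3: float = np.nan
    normalized_eigenvalues: np.ndarray | None = None
    sphericalness: float = np.nan
    location_mm: np.ndarray | None = None
    segmentation: object = None
    teeth: object = None

    def as_row(self) -> dict:
        e = self.normalized_eigenvalues
        loc = self.location_mm
        return {
            "mouse_id": self.mouse_id,
            "date": self.date,
            "volume_mm3": self.volume_mm3,
            "e1": e[0] if e is not None else np.nan,
            "e2": e[1] if e is not None else np.nan,
            "e3": e[2] if e is not None else np.nan,
            "sphericalness": self.sphericalness,
            "loc_lateral_mm": loc[0] if loc is not None else np.nan,
            "loc_ap_mm": loc[1] if loc is not None else np.nan,
            "loc_vertical_mm": loc[2] if loc is not None else np.nan,
            "status": self.status,
        }


def segment_mouse(
    vol: ScanVolume,
    config: SegmentationConfig | None = None,
    mouse_id: str = "",
    date: str = "",
) -> MouseResult:
    """Full head-segmentation chain for one cleaned single-mouse volume."""
    cfg = config or SegmentationConfig()
    result = MouseResult(mouse_id=mouse_id, date=date)
    teeth = segment_teeth(vol)
    bone = segment_bone(vol, teeth)
    chain = build_symmetry_chain(bone, teeth)
    grid = build_grid(
        chain,
        vol.spacing_mm,
        standard_shape=cfg.standard_shape,
        lateral_halfwidth_mm=cfg.lateral_halfwidth_mm,
    )
    if cfg.refine_steps > 0:
        grid = refine_grid(
            grid,
            vol,
            lambda_curv=cfg.lambda_curv,
            max_steps=cfg.refine_steps,
            max_disp_mm=cfg.max_disp_mm,
        )
    head = resample_head(vol, grid)
    hm = filter_height_map(
        excess_height_map(head, cfg.tumor_side),
        min_thickness_mm=cfg.min_thickness_mm,
        smooth_mm=cfg.smooth_mm,
    )
    seg = backproject_tumor(hm, grid, head, vol, mouse_id=mouse_id, scan_date=date)
    result.segmentation = seg
    result.teeth = teeth
    result.volume_mm3 = seg.volume_mm3
    if seg.mask.sum() >= 4:
        try:
            metrics = shape_eigen(seg)
            result.normalized_eigenvalues = metrics.normalized
            result.sphericalness = sphericalness(seg)
            result.location_mm = tumor_location(seg, teeth)
        except ValueError:
            pass  # degenerate (near-planar) mask: volume still reported
    return result


def _read_sheet(sheet) -> pd.DataFrame:
    if isinstance(sheet, pd.DataFrame):
        return sheet
    path = Path(sheet)
    if not path.exists():
        raise FileNotFoundError(f"task sheet not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _row_mouse_ids(row, capacity: int) -> list[str]:
    raw = str(row.get("mouse_ids", "") or "")
    ids = [t.strip() for t in raw.split(";") if t.strip()]
    if len(ids) > capacity:
        raise ValueError(f"{len(ids)} mouse IDs for a {capacity}-slot layout")
    ids += [f"slot{i + 1}" for i in range(len(ids), capacity)]
    return ids


def run_tasks(
    sheet,
    config: SegmentationConfig | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Process every scan in a task table; returns (results, per-scan logs).

    Expected columns: ``scan`` (path), ``layout`` (three_row / five_holder /
    single), ``expected_n``, ``mouse_ids`` (semicolon-separated, in slot
    order) and optionally ``date``.  Any single scan failure is recorded and
    the batch continues.
    """
    df = _read_sheet(sheet)
    cfg = config or SegmentationConfig()
    rows: list[dict] = []
    logs: list[dict] = []
    for _, task in df.iterrows():
        date = str(task.get("date", "") or "")
        layout = str(task.get("layout", "three_row"))
        log: dict = {"scan": str(task.get("scan", "")), "layout": layout, "errors": []}
        try:
            capacity = LAYOUT_CAPACITY[layout]
            expected = int(task.get("expected_n", capacity) or capacity)
            ids = _row_mouse_ids(task, capacity)
            vol = mio.load_nifti(task["scan"])
            vol = calibrate_intensity(vol)
            if layout == "single":
                subvols = [vol]
            else:
                split = split_multimouse(vol, layout, expected)
                subvols = split.volumes
                log["split"] = {
                    k: v for k, v in split.split_coords.items()
                }
        except Exception as exc:  # scan-level failure: mark all its slots
            log["errors"].append("".join(traceback.format_exception_only(exc)).strip())
            logs.append(log)
            for mid in _row_mouse_ids(task, LAYOUT_CAPACITY.get(layout, 1)):
                rows.append(
                    MouseResult(mid, date=date, status="scan_failed").as_row()
                )
            continue

        for slot, sub in enumerate(subvols):
            mid = ids[slot] if slot < len(ids) else f"slot{slot + 1}"
            try:
                cleaned, occupied = clean_single_mouse(sub, layout)
                if not occupied:
                    rows.append(MouseResult(mid, date=date, status="empty").as_row())
                    continue
                res = segment_mouse(cleaned, cfg, mouse_id=mid, date=date)
                rows.append(res.as_row())
                if out_dir is not None and res.segmentation is not None:
                    out = Path(out_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    from .voxcore import BinaryMask

                    mio.save_mask_nifti(
                        BinaryMask(res.segmentation.mask, cleaned.spacing_mm),
                        cleaned.origin_mm,
                        out / f"{mid}_{date or 'nodate'}_tumor.nii.gz",
                    )
            except Exception as exc:
                log["errors"].append(
                    f"{mid}: " + "".join(traceback.format_exception_only(exc)).strip()
                )
                rows.append(MouseResult(mid, date=date, status="failed").as_row())
        logs.append(log)
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results = results.sort_values(["mouse_id", "date"], kind="mergesort").reset_index(
        drop=True
    )
    return results, logs


def export_results(results: pd.DataFrame, path) -> pd.DataFrame:
    """Write results to CSV (or XLSX) in deterministic (mouse, date) order."""
    out = results.sort_values(["mouse_id", "date"], kind="mergesort").reset_index(drop=True)
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        out.to_excel(path, index=False)
    else:
        out.to_csv(path, index=False, float_format="%.9g")
    return out
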