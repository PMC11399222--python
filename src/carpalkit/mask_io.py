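"""Reading and writing of label masks, contours, sidecars and reports.

All geometry leaves this module in millimetres: pixel coordinates never
propagate past ingestion.  A label mask is a PNG/TIFF image of integer
labels (one per bone, background 0) accompanied by a JSON sidecar giving
the pixel spacing in mm/px, the radiographic view and the patient age —
without the spacing no measurement is meaningful, so a missing spacing is
fatal while missing bones merely make the dependent measurements
unavailable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure as _skmeasure

from .geometry import (
    ensure_ccw,
    polyline_length,
    resample_polyline,
    shoelace_area,
)

FORMAT_VERSION = "1.0"


class View(str, Enum):
    """Radiographic views handled by the pipeline."""

    NEUTRAL_AP_PA = "neutral_ap_pa"
    ULNAR_DEVIATED_AP_PA = "ulnar_deviated_ap_pa"
    CLENCHED_FIST_AP_PA = "clenched_fist_ap_pa"
    LATERAL = "lateral"
    OBLIQUE = "oblique"

    @property
    def is_frontal(self) -> bool:
        return self in (
            View.NEUTRAL_AP_PA,
            View.ULNAR_DEVIATED_AP_PA,
            View.CLENCHED_FIST_AP_PA,
        )


class Bone(str, Enum):
    SCAPHOID = "scaphoid"
    LUNATE = "lunate"
    TRIQUETRUM = "triquetrum"
    CAPITATE = "capitate"
    HAMATE = "hamate"
    METACARPAL3 = "metacarpal3"
    RADIUS = "radius"


#: Fixed label table used by the rasteriser and the readers.
LABEL_TABLE: dict[Bone, int] = {
    Bone.SCAPHOID: 1,
    Bone.LUNATE: 2,
    Bone.TRIQUETRUM: 3,
    Bone.CAPITATE: 4,
    Bone.HAMATE: 5,
    Bone.METACARPAL3: 6,
    Bone.RADIUS: 7,
}


class MaskIOError(Exception):
    """Unreadable mask, missing sidecar or invalid calibration."""


class SegmentationError(Exception):
    """A mask is empty/degenerate or has multiple components."""


@dataclass
class StudyMeta:
    """Calibration and context that gate every measurement rule."""

    spacing_mm_per_px: float
    view: View
    age_years: float = 40.0
    study_id: str = ""

    def __post_init__(self):
        self.view = View(self.view)
        if not (self.spacing_mm_per_px > 0):
            raise MaskIOError("pixel spacing must be > 0 mm/px")
        if self.age_years < 0:
            raise MaskIOError("age_years must be >= 0")


@dataclass
class Contour:
    """Closed, simple, counter-clockwise bone outline in mm.

    The closing edge is implicit: the first point is not repeated.
    """

    bone: Bone
    points: np.ndarray

    def __post_init__(self):
        self.bone = Bone(self.bone)
        pts = np.asarray(self.points, dtype=float)
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 distinct points")
        self.points = ensure_ccw(pts)

    @property
    def area_mm2(self) -> float:
        return abs(shoelace_area(self.points))

    @property
    def perimeter_mm(self) -> float:
        return polyline_length(self.points, closed=True)


@dataclass
class MaskStudy:
    """One ingested view: per-bone binary masks plus metadata."""

    masks: dict[Bone, np.ndarray]
    meta: StudyMeta
    missing: list[Bone] = field(default_factory=list)


# ---------------------------------------------------------------------------
# masks + sidecars


def write_label_mask(path, label_image: np.ndarray, meta: StudyMeta,
                     extra_sidecar: dict | None = None) -> None:
    path = Path(path)
    img = np.asarray(label_image)
    if img.max() > 255:
        raise MaskIOError("label values exceed uint8 range")
    Image.fromarray(img.astype(np.uint8), mode="L").save(path)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "spacing_mm_per_px": meta.spacing_mm_per_px,
        "view": meta.view.value,
        "age_years": meta.age_years,
        "study_id": meta.study_id,
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sidecar(path) -> tuple[StudyMeta, dict]:
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"sidecar not found: {path}")
    raw = json.loads(path.read_text())
    if "spacing_mm_per_px" not in raw:
        raise MaskIOError(f"sidecar {path} lacks spacing_mm_per_px (fatal: "
                          "measurements are in mm)")
    meta = StudyMeta(
        spacing_mm_per_px=raw["spacing_mm_per_px"],
        view=raw.get("view", View.NEUTRAL_AP_PA),
        age_years=raw.get("age_years", 40.0),
        study_id=raw.get("study_id", ""),
    )
    return meta, raw


def read_label_mask(path, label_table: dict[Bone, int] | None = None) -> MaskStudy:
    """Read a label mask and its sidecar into per-bone binary masks.

    Bones absent from the image are reported in ``missing`` rather than
    raising: downstream measurements that need them become unavailable.
    """
    path = Path(path)
    if label_table is None:
        label_table = LABEL_TABLE
    try:
        img = np.asarray(Image.open(path))
    except Exception as exc:  # unreadable file is fatal
        raise MaskIOError(f"cannot read mask {path}: {exc}") from exc
    meta, _ = read_sidecar(path.with_suffix(".json"))
    masks: dict[Bone, np.ndarray] = {}
    missing: list[Bone] = []
    for bone, label in label_table.items():
        m = img == label
        if m.any():
            masks[bone] = m
        else:
            missing.append(bone)
    return MaskStudy(masks=masks, meta=meta, missing=missing)


# ---------------------------------------------------------------------------
# contour extraction


def extract_contour(mask: np.ndarray, spacing_mm_per_px: float,
                    bone: Bone = Bone.LUNATE) -> Contour:
    """Sub-pixel boundary of a single-component binary mask, in mm.

    Marching squares at the 0.5 iso-level; pixel (row i, col j) has its
    centre at (x, y) = (j, i) * spacing.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    n_comp = _skmeasure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise SegmentationError(
            f"expected exactly one connected component, found {n_comp}")
    if mask.sum() < 4:
        raise SegmentationError("mask too small for sub-pixel contouring")
    padded = np.pad(mask.astype(float), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    outline = max(contours, key=len)
    rc = outline - 1.0  # undo padding
    pts = np.column_stack([rc[:, 1], rc[:, 0]]) * spacing_mm_per_px
    return Contour(bone=bone, points=pts)


def resample_arclength(points, n: int, closed: bool = False) -> np.ndarray:
    """Resample a polyline/contour to ``n`` arc-length-uniform points."""
    return resample_polyline(points, n, closed=closed)


# ---------------------------------------------------------------------------
# contour JSON


def write_contours(path, contours: dict[Bone, Contour]) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "contours": {
            Bone(b).value: np.asarray(c.points).round(6).tolist()
            for b, c in contours.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_contours(path) -> dict[Bone, Contour]:
    raw = json.loads(Path(path).read_text())
    return {
        Bone(b): Contour(bone=Bone(b), points=np.asarray(pts))
        for b, pts in raw["contours"].items()
    }


# ---------------------------------------------------------------------------
# reports

REPORT_FIELDS = [
    "study_id", "sl_distance_mm", "sl_angle_deg", "cl_angle_deg",
    "disruption_score", "arc_interrupted",
]


def write_report(results: dict, json_path, csv_path=None) -> dict:
    """Write a study (or cohort) report as JSON and optionally CSV.

    ``results`` may be one study dict or {"studies": [...]}; floats are
    rounded to 6 decimals so equal runs produce byte-identical files.
    """
    def _round(obj):
        if isinstance(obj, float):
            return round(obj, 6)
        if isinstance(obj, dict):
            return {k: _round(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_round(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return _round(obj.tolist())
        if isinstance(obj, (np.floating,)):
            return round(float(obj), 6)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return obj

    payload = {"format_version": FORMAT_VERSION}
    payload.update(_round(results))
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if csv_path is not None:
        studies = results.get("studies", [results])
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_FIELDS)
            writer.writeheader()
            for st in studies:
                writer.writerow({k: _round(st.get(k)) for k in REPORT_FIELDS})
    return payload


def read_report(json_path) -> dict:
    return json.loads(Path(json_path).read_text())
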