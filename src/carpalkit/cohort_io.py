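"""Loading synthesized cohorts and report directories from disk."""

from __future__ import annotations

import json
from pathlib import Path

from .arcs import build_arcs
from .mask_io import Bone, MaskIOError, read_label_mask, read_contours, read_sidecar
from .synthetic import SyntheticCase, WristParams


def load_case(case_dir) -> SyntheticCase:
    """Rebuild a synthetic case from its on-disk representation."""
    case_dir = Path(case_dir)
    meta, raw = read_sidecar(case_dir / "ap_mask.json")
    truth = raw.get("truth")
    truth_facets = raw.get("truth_facets")
    if truth is None or truth_facets is None:
        raise MaskIOError(f"{case_dir}: sidecar lacks ground truth "
                          "(not a synthesized cohort?)")
    params = WristParams(
        sl_gap_mm=truth["sl_distance_mm"],
        sl_angle_deg=truth["sl_angle_deg"],
        cl_angle_deg=truth["cl_angle_deg"],
        subluxation_mm=truth["subluxation_mm"],
        age_years=meta.age_years,
    )
    contours_ap = read_contours(case_dir / "ap_contours.json")
    contours_lat = read_contours(case_dir / "lateral_contours.json")
    ap = read_label_mask(case_dir / "ap_mask.png")
    lat = read_label_mask(case_dir / "lateral_mask.png")

    def _label_image(study):
        import numpy as np

        from .mask_io import LABEL_TABLE

        shape = next(iter(study.masks.values())).shape
        img = np.zeros(shape, dtype="uint8")
        for bone, mask in study.masks.items():
            img[mask] = LABEL_TABLE[bone]
        return img

    return SyntheticCase(
        params=params, contours_ap=contours_ap, contours_lat=contours_lat,
        truth=truth, truth_facets=truth_facets,
        label_mask_ap=_label_image(ap), label_mask_lat=_label_image(lat),
        spacing_mm_per_px=meta.spacing_mm_per_px)


def case_dirs(cohort_dir) -> list[Path]:
    dirs = sorted(p for p in Path(cohort_dir).iterdir()
                  if p.is_dir() and (p / "ap_mask.json").exists())
    if not dirs:
        raise MaskIOError(f"no cases found in {cohort_dir}")
    return dirs


def load_cohort(cohort_dir) -> list[SyntheticCase]:
    return [load_case(d) for d in case_dirs(cohort_dir)]


def truth_record(case: SyntheticCase, case_id: str) -> dict:
    """Ground-truth evaluation record (incl. truth arcs) of one case."""
    from .pipeline import truth_shapes

    arcset = build_arcs(truth_shapes(case, "ap"))
    return {
        "case_id": case_id,
        "sl_distance_mm": case.truth["sl_distance_mm"],
        "sl_angle_deg": case.truth["sl_angle_deg"],
        "cl_angle_deg": case.truth["cl_angle_deg"],
        "interrupted": case.truth["interrupted"],
        "arcs": {name: arc.tolist() for name, arc in arcset.items()},
    }


def load_truth_records(cohort_dir) -> list[dict]:
    return [truth_record(load_case(d), d.name) for d in case_dirs(cohort_dir)]


def load_pred_reports(pred_dir) -> list[dict]:
    paths = sorted(Path(pred_dir).glob("*_report.json"))
    if not paths:
        raise MaskIOError(f"no *_report.json files in {pred_dir}")
    out = []
    for p in paths:
        rep = json.loads(p.read_text())
        rep["case_id"] = rep.get("study_id") or p.stem.replace("_report", "")
        out.append(rep)
    return out
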