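"""End-to-end orchestration: ingest → shape fitting → measurements →
arc assessment → report, plus model training and cohort evaluation.

A *study* is a directory with an AP/PA and/or lateral label mask
(``ap_mask.png`` / ``lateral_mask.png``) and JSON sidecars.  Outputs
depend on the provided views: AP/PA yields the SL joint distance and the
carpal-arc assessment, the lateral view yields the SL and CL angles;
anything whose view or bones are missing is reported explicitly as
unavailable, never silently omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import arcs as _arcs
from . import measurements as _meas
from .mask_io import (
    LABEL_TABLE,
    Bone,
    MaskStudy,
    SegmentationError,
    View,
    extract_contour,
    read_label_mask,
    write_report,
)
from .measurements import ThresholdConfig
from .shape_model import (
    ContourFit,
    LandmarkedShape,
    PointDistributionModel,
    fit_to_contour,
)
from .synthetic import SyntheticCase

#: bones fitted per view (only what the measurements and arcs need)
AP_BONES = [Bone.SCAPHOID, Bone.LUNATE, Bone.TRIQUETRUM,
            Bone.CAPITATE, Bone.HAMATE]
LAT_BONES = [Bone.SCAPHOID, Bone.LUNATE, Bone.CAPITATE]


class ModelMissingError(FileNotFoundError):
    """A required shape-model file is absent."""


@dataclass
class PipelineConfig:
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    variance_target: float = 0.95
    residual_floor_mm: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib
            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        thr = ThresholdConfig.from_dict(raw.get("thresholds", {}))
        return cls(thresholds=thr,
                   variance_target=raw.get("variance_target", 0.95),
                   residual_floor_mm=raw.get("residual_floor_mm", 0.05),
                   seed=raw.get("seed", 0))


@dataclass
class ModelRegistry:
    """Trained bone PDMs (per view) and the arc interruption detector."""

    bone_models: dict[tuple[str, Bone], PointDistributionModel]
    detector: _arcs.ArcInterruptionDetector | None = None

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = []
        for (view_key, bone), model in self.bone_models.items():
            name = f"bone_{view_key}_{bone.value}"
            model.save(out_dir / name)
            names.append(name)
        det_meta = None
        if self.detector is not None:
            for arc_name, model in self.detector.models_.items():
                model.save(out_dir / f"arc_{arc_name}")
            det_meta = {
                "z_crit": self.detector.z_crit,
                "threshold": self.detector.threshold,
                "variance_target": self.detector.variance_target,
                "residual_floor_mm": self.detector.residual_floor_mm,
                "clamp_sd": self.detector.clamp_sd,
                "n_training": self.detector.n_training_,
            }
        manifest = {
            "format_version": "1.0",
            "bone_models": names,
            "detector": det_meta,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, model_dir) -> "ModelRegistry":
        model_dir = Path(model_dir)
        manifest_path = model_dir / "manifest.json"
        if not manifest_path.exists():
            raise ModelMissingError(f"no model manifest in {model_dir}")
        manifest = json.loads(manifest_path.read_text())
        bone_models = {}
        for name in manifest["bone_models"]:
            _, view_key, bone = name.split("_", 2)
            path = model_dir / name
            if not path.with_suffix(".npz").exists():
                raise ModelMissingError(f"missing model file {path}")
            bone_models[(view_key, Bone(bone))] = PointDistributionModel.load(path)
        detector = None
        if manifest.get("detector"):
            dm = manifest["detector"]
            detector = _arcs.ArcInterruptionDetector(
                z_crit=dm["z_crit"], threshold=dm["threshold"],
                variance_target=dm["variance_target"],
                residual_floor_mm=dm["residual_floor_mm"],
                clamp_sd=dm["clamp_sd"])
            detector.models_ = {
                name: PointDistributionModel.load(model_dir / f"arc_{name}")
                for name in _arcs.ARC_NAMES}
            detector.n_training_ = dm["n_training"]
        return cls(bone_models=bone_models, detector=detector)


# ---------------------------------------------------------------------------
# training


def _case_landmarks(case: SyntheticCase, view_key: str, bone: Bone):
    """Training landmarks (the template-corresponded contour vertices)
    and facet ranges of one bone of one case."""
    contours = case.contours_ap if view_key == "ap" else case.contours_lat
    facets = case.truth_facets[view_key][bone.value]
    return contours[bone].points, {k: tuple(v) for k, v in facets.items()}


def truth_shapes(case: SyntheticCase, view_key: str = "ap") -> dict[Bone, LandmarkedShape]:
    """Ground-truth landmarked shapes of a synthetic case."""
    bones = AP_BONES if view_key == "ap" else LAT_BONES
    out = {}
    for bone in bones:
        pts, fac = _case_landmarks(case, view_key, bone)
        out[bone] = LandmarkedShape(bone=bone, landmarks=pts, facets=fac)
    return out


def train_models(cases: list[SyntheticCase], config: PipelineConfig | None = None,
                 out_dir=None,
                 detector_params: dict | None = None) -> ModelRegistry:
    """Train per-bone PDMs and the arc detector from annotated normals.

    Bone models are built from the corresponded training contours; the
    arc detector is then trained on arcs *measured by the pipeline
    itself* on the normal cases (masks → contours → fitted shapes →
    arcs), so its residual scales include measurement noise and held-out
    normal wrists score near z = 1.
    """
    config = config or PipelineConfig()
    normals = [c for c in cases if not c.truth["interrupted"]]
    if len(normals) < 10:
        raise ValueError(f"insufficient normal cases for training "
                         f"({len(normals)} < 10)")

    bone_models = {}
    for view_key, bones in (("ap", AP_BONES), ("lateral", LAT_BONES)):
        for bone in bones:
            stack, fac = [], None
            for c in normals:
                pts, fac = _case_landmarks(c, view_key, bone)
                stack.append(pts)
            model = PointDistributionModel(
                variance_target=config.variance_target,
                residual_floor_mm=config.residual_floor_mm)
            model.fit(np.stack(stack), facets=fac, bone=bone)
            bone_models[(view_key, bone)] = model

    registry = ModelRegistry(bone_models=bone_models)

    arcsets = []
    for c in normals:
        if c.label_mask_ap is not None:
            study = MaskStudy(
                masks={b: c.label_mask_ap == lbl
                       for b, lbl in LABEL_TABLE.items()
                       if (c.label_mask_ap == lbl).any()},
                meta=c.meta(View.NEUTRAL_AP_PA))
            shapes, _ = fit_view(study, registry, "ap")
        else:
            shapes = truth_shapes(c, "ap")
        arcsets.append(_arcs.build_arcs(shapes))

    det_kwargs = dict(z_crit=config.thresholds.z_crit,
                      threshold=config.thresholds.arc_detection_threshold,
                      variance_target=config.variance_target,
                      residual_floor_mm=config.residual_floor_mm)
    if detector_params:
        det_kwargs.update(detector_params)
    registry.detector = _arcs.ArcInterruptionDetector(**det_kwargs).fit(arcsets)

    if out_dir is not None:
        registry.save(out_dir)
    return registry


# ---------------------------------------------------------------------------
# measurement of one study


def fit_view(study: MaskStudy, registry: ModelRegistry, view_key: str):
    """Extract contours and fit the view's bone models.

    Returns (shapes, issues): bones whose mask is missing or whose
    segmentation is unusable are skipped and reported in ``issues``.
    """
    bones = AP_BONES if view_key == "ap" else LAT_BONES
    shapes: dict[Bone, LandmarkedShape] = {}
    issues: list[str] = []
    for bone in bones:
        if bone not in study.masks:
            issues.append(f"{bone.value}: missing from mask")
            continue
        key = (view_key, bone)
        if key not in registry.bone_models:
            raise ModelMissingError(f"no trained model for {key}")
        try:
            contour = extract_contour(study.masks[bone],
                                      study.meta.spacing_mm_per_px, bone)
        except SegmentationError as exc:
            issues.append(f"{bone.value}: {exc}")
            continue
        fit: ContourFit = fit_to_contour(registry.bone_models[key], contour)
        if not fit.converged:
            issues.append(f"{bone.value}: fit not converged "
                          f"(residual {fit.residual_mm:.3f} mm)")
        shapes[bone] = fit.shape
    return shapes, issues


def _unavailable(reason: str) -> dict:
    return {"value": None, "abnormal": None, "unavailable_reason": reason}


def _meas_dict(res: _meas.MeasurementResult) -> dict:
    return {"value": res.value, "abnormal": res.abnormal,
            "threshold_rule": res.threshold_rule}


def run_study(study_dir, registry: ModelRegistry,
              config: PipelineConfig | None = None,
              out_dir=None) -> dict:
    """Measure one study directory; returns (and optionally writes) the
    report with the five outputs: SL distance, SL angle, CL angle, arc
    polylines and the arc disruption assessment."""
    config = config or PipelineConfig()
    study_dir = Path(study_dir)
    thr = config.thresholds

    ap_path = study_dir / "ap_mask.png"
    lat_path = study_dir / "lateral_mask.png"
    if not ap_path.exists() and not lat_path.exists():
        raise FileNotFoundError(f"no usable view in {study_dir}")

    report: dict = {"study_id": study_dir.name, "issues": [],
                    "thresholds_used": thr.to_dict()}
    for k in ("sl_distance_mm", "sl_angle_deg", "cl_angle_deg"):
        report[k] = None

    if ap_path.exists():
        study = read_label_mask(ap_path)
        report["study_id"] = study.meta.study_id or report["study_id"]
        shapes, issues = fit_view(study, registry, "ap")
        report["issues"] += [f"ap/{s}" for s in issues]
        age = study.meta.age_years
        if Bone.SCAPHOID in shapes and Bone.LUNATE in shapes:
            try:
                res = _meas.sl_distance(shapes[Bone.SCAPHOID], shapes[Bone.LUNATE],
                                        view=study.meta.view, age_years=age,
                                        config=thr)
                report["sl_distance"] = _meas_dict(res)
                report["sl_distance_mm"] = res.value
            except _meas.UnclassifiableError as exc:
                report["sl_distance"] = _unavailable(str(exc))
        else:
            report["sl_distance"] = _unavailable("scaphoid or lunate unavailable")

        if study.meta.view == View.NEUTRAL_AP_PA:
            arcset = _arcs.build_arcs(shapes, view=study.meta.view)
            report["arcs"] = {name: arc.tolist() for name, arc in arcset.items()}
            if registry.detector is None:
                report["arc_assessment"] = _unavailable("no arc models trained")
            elif len(arcset.available) == 0:
                report["arc_assessment"] = _unavailable(
                    "no arc could be built (missing bones)")
            else:
                assessment = registry.detector.assess(arcset)
                report["arc_assessment"] = {
                    "disruption_score": assessment.disruption_score,
                    "detected": assessment.detected,
                    "threshold": assessment.threshold,
                    "z_crit": assessment.z_crit,
                    "available_arcs": arcset.available,
                    "zscores": {k: v.tolist()
                                for k, v in assessment.zscores.items()},
                    "markers": {k: [list(r) for r in v]
                                for k, v in assessment.markers.items()},
                }
                report["disruption_score"] = assessment.disruption_score
                report["arc_interrupted"] = assessment.detected
                if out_dir is not None:
                    from PIL import Image

                    overlay = _arcs.render_heatmap(
                        assessment, _label_image(study) * 30,
                        study.meta.spacing_mm_per_px)
                    Path(out_dir).mkdir(parents=True, exist_ok=True)
                    Image.fromarray(overlay).save(
                        Path(out_dir) / f"{report['study_id']}_arcs.png")
        else:
            report["arcs"] = _unavailable(
                "carpal arcs require the neutral AP/PA view")
            report["arc_assessment"] = _unavailable(
                "carpal arcs require the neutral AP/PA view")
    else:
        report["sl_distance"] = _unavailable("no AP/PA view")
        report["arcs"] = _unavailable("no AP/PA view")
        report["arc_assessment"] = _unavailable("no AP/PA view")

    if lat_path.exists():
        study = read_label_mask(lat_path)
        shapes, issues = fit_view(study, registry, "lateral")
        report["issues"] += [f"lateral/{s}" for s in issues]
        age = study.meta.age_years
        pairs = [("sl_angle", _meas.sl_angle, Bone.SCAPHOID),
                 ("cl_angle", _meas.cl_angle, Bone.CAPITATE)]
        for name, fn, bone in pairs:
            if bone in shapes and Bone.LUNATE in shapes:
                res = fn(shapes[bone], shapes[Bone.LUNATE],
                         view=study.meta.view, age_years=age, config=thr)
                report[name] = _meas_dict(res)
                report[f"{name}_deg"] = res.value
            else:
                report[name] = _unavailable(
                    f"{bone.value} or lunate unavailable")
    else:
        report["sl_angle"] = _unavailable("no lateral view")
        report["cl_angle"] = _unavailable("no lateral view")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / f"{report['study_id']}_report.json",
                     out_dir / f"{report['study_id']}_report.csv")
    return report


def _label_image(study: MaskStudy) -> np.ndarray:
    from .mask_io import LABEL_TABLE

    shape = next(iter(study.masks.values())).shape
    img = np.zeros(shape, dtype=np.uint8)
    for bone, mask in study.masks.items():
        img[mask] = LABEL_TABLE[bone]
    return img


def case_study(case: SyntheticCase, view: View) -> MaskStudy:
    """Wrap a synthetic case's label mask as an in-memory MaskStudy."""
    mask = case.label_mask_ap if view.is_frontal else case.label_mask_lat
    if mask is None:
        raise ValueError("case was generated without masks")
    masks = {b: mask == lbl for b, lbl in LABEL_TABLE.items()
             if (mask == lbl).any()}
    return MaskStudy(masks=masks, meta=case.meta(view))


def measure_case(case: SyntheticCase, registry: ModelRegistry,
                 config: PipelineConfig | None = None) -> dict:
    """Measure a synthetic case in memory (masks → contours → fits →
    measurements + arc assessment); returns a flat record."""
    config = config or PipelineConfig()
    thr = config.thresholds
    rec: dict = {}

    ap = case_study(case, View.NEUTRAL_AP_PA)
    shapes, issues = fit_view(ap, registry, "ap")
    rec["issues"] = list(issues)
    res = _meas.sl_distance(shapes[Bone.SCAPHOID], shapes[Bone.LUNATE],
                            view=ap.meta.view, age_years=ap.meta.age_years,
                            config=thr)
    rec["sl_distance_mm"] = res.value
    rec["sl_distance_abnormal"] = res.abnormal

    arcset = _arcs.build_arcs(shapes)
    rec["arcs"] = {name: arc for name, arc in arcset.items()}
    if registry.detector is not None:
        assessment = registry.detector.assess(arcset)
        rec["disruption_score"] = assessment.disruption_score
        rec["arc_interrupted"] = assessment.detected

    lat = case_study(case, View.LATERAL)
    shapes, issues = fit_view(lat, registry, "lateral")
    rec["issues"] += issues
    rec["sl_angle_deg"] = _meas.sl_angle(
        shapes[Bone.SCAPHOID], shapes[Bone.LUNATE],
        age_years=lat.meta.age_years, config=thr).value
    rec["cl_angle_deg"] = _meas.cl_angle(
        shapes[Bone.CAPITATE], shapes[Bone.LUNATE],
        age_years=lat.meta.age_years, config=thr).value
    return rec


# ---------------------------------------------------------------------------
# cohort evaluation


def evaluate_records(preds: list[dict], truths: list[dict],
                     seed: int = 0, iters: int = 1000) -> dict:
    """Full metric stack on matched prediction/truth records.

    Records are matched by ``case_id``; measurement agreement (MAE, bias,
    LoA with stratified bootstrap CIs), per-arc mean Fréchet distance,
    and ROC/Youden detection metrics are emitted for whatever fields are
    present in both.
    """
    from . import evalstats as ev

    tmap = {t["case_id"]: t for t in truths}
    matched = [(p, tmap[p["case_id"]]) for p in preds if p["case_id"] in tmap]
    if len(matched) != len(preds) or len(matched) != len(truths):
        raise ValueError("case_id mismatch between predictions and truth")

    out: dict = {"n": len(matched)}
    specs = [("sl_distance_mm", ev.distance_strata),
             ("sl_angle_deg", ev.angle_strata),
             ("cl_angle_deg", ev.angle_strata)]
    for key, strata_rule in specs:
        pairs = [(p[key], t[key]) for p, t in matched
                 if p.get(key) is not None and t.get(key) is not None]
        if len(pairs) >= 2:
            pred, truth = map(np.asarray, zip(*pairs))
            rep = ev.measurement_agreement(pred, truth,
                                           strata=strata_rule(truth),
                                           iters=iters, seed=seed)
            out[key.rsplit("_", 1)[0]] = rep.to_dict()

    for arc_name in _arcs.ARC_NAMES:
        pairs = [(np.asarray(p["arcs"][arc_name]), np.asarray(t["arcs"][arc_name]))
                 for p, t in matched
                 if isinstance(p.get("arcs"), dict) and isinstance(t.get("arcs"), dict)
                 and p["arcs"].get(arc_name) is not None
                 and t["arcs"].get(arc_name) is not None]
        if pairs:
            mfd, _, ci = ev.mean_frechet([a for a, _ in pairs],
                                         [b for _, b in pairs],
                                         iters=iters, seed=seed)
            out[f"mfd_{arc_name}"] = {"value": mfd, "n": len(pairs),
                                      "ci": ci.as_list() if ci else None}

    det = [(p["disruption_score"], t["interrupted"]) for p, t in matched
           if p.get("disruption_score") is not None
           and t.get("interrupted") is not None]
    if det:
        scores, labels = map(np.asarray, zip(*det))
        if labels.any() and not labels.all():
            roc = ev.roc_analysis(scores, labels, iters=iters, seed=seed)
            out["arc_detection"] = roc.to_dict()
    return out
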