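"""Carpal instability measurements and their threshold classification.

Implements the three radiographic measurements used to screen for carpal
instability and the reference thresholds against which each is judged:

* **SL joint distance** — Euclidean distance between the mid-points of
  the facing scaphoid–lunate facets on an AP/PA view; abnormal above
  3.0 mm (neutral) or 3.7 mm (ulnar-deviated, Stecher's projection).
* **SL angle** — angle between the scaphoid long axis and the lunate
  mid-plane axis on the lateral view; normal between 30 and 60 degrees.
* **CL angle** — angle between the capitate long axis and the lunate
  axis on the lateral view; normal up to 30 degrees.

Axis construction: the capitate axis joins the mid-points of its lunate
and third-metacarpal facets, the lunate mid-plane axis joins the
mid-points of its radius and capitate facets, and the scaphoid long axis
is the principal (major) axis of its lateral contour.  All axes are
canonically oriented distally (negative image-y); this makes the angle
between two axes well defined in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mask_io import View
from .shape_model import LandmarkedShape, facet_midpoint


class AmbiguousAxisError(ValueError):
    """Near-isotropic shape: the principal axis is not well defined."""


class UnclassifiableError(ValueError):
    """No applicable threshold (e.g. pediatric age without a table entry)."""


@dataclass
class Axis:
    """Anchored unit direction, canonically oriented distally."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("zero-length axis direction")
        self.direction = _orient_distal(d / norm)


def _orient_distal(d: np.ndarray) -> np.ndarray:
    """Flip a unit vector so it points distally (negative image-y;
    ties broken toward positive x)."""
    if d[1] > 0 or (d[1] == 0 and d[0] < 0):
        return -d
    return d


@dataclass
class MeasurementResult:
    name: str                  # sl_distance | sl_angle | cl_angle
    value: float               # mm or degrees
    abnormal: bool | None
    threshold_rule: str
    view: View
    age_years: float


@dataclass
class ThresholdConfig:
    """Reference thresholds; all defaults are the adult literature values.

    The pediatric SL-distance table (age-band upper limits for 6–14
    year-olds) ships empty: values must be supplied by the user from the
    age-specific reference literature.  Clenched-fist views use the
    neutral threshold (flagged as an assumption in reports).
    """

    sl_distance_neutral_mm: float = 3.0
    sl_distance_ulnar_mm: float = 3.7
    sl_angle_range_deg: tuple[float, float] = (30.0, 60.0)
    cl_angle_max_deg: float = 30.0
    #: age-band -> SL distance upper limit, e.g. {"6-8": 2.6, "9-11": ...}
    pediatric_sl_table: dict[str, float] = field(default_factory=dict)
    pediatric_age_max: float = 14.0
    arc_detection_threshold: float = 0.11
    z_crit: float = 2.0

    def __post_init__(self):
        for v in (self.sl_distance_neutral_mm, self.sl_distance_ulnar_mm,
                  self.cl_angle_max_deg, self.arc_detection_threshold,
                  self.z_crit):
            if not (v > 0):
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        kwargs = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "sl_angle_range_deg" in kwargs:
            kwargs["sl_angle_range_deg"] = tuple(kwargs["sl_angle_range_deg"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "sl_distance_neutral_mm": self.sl_distance_neutral_mm,
            "sl_distance_ulnar_mm": self.sl_distance_ulnar_mm,
            "sl_angle_range_deg": list(self.sl_angle_range_deg),
            "cl_angle_max_deg": self.cl_angle_max_deg,
            "pediatric_sl_table": dict(self.pediatric_sl_table),
            "pediatric_age_max": self.pediatric_age_max,
            "arc_detection_threshold": self.arc_detection_threshold,
            "z_crit": self.z_crit,
        }


# ---------------------------------------------------------------------------
# axes


def principal_axis(shape: LandmarkedShape, min_eigen_ratio: float = 1.05) -> Axis:
    """Major axis of the landmark second-central-moment matrix.

    Raises :class:`AmbiguousAxisError` when the eigenvalue ratio is below
    ``min_eigen_ratio`` (near-circular shape, direction meaningless).
    """
    pts = shape.landmarks
    if len(pts) < 3:
        raise ValueError("need at least 3 landmarks")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0 or eigvals[1] / max(eigvals[0], 1e-300) < min_eigen_ratio:
        raise AmbiguousAxisError(
            f"{shape.bone.value}: eigenvalue ratio "
            f"{eigvals[1] / max(eigvals[0], 1e-300):.3f} < {min_eigen_ratio}")
    return Axis(anchor=pts.mean(axis=0), direction=eigvecs[:, 1])


def facet_axis(shape: LandmarkedShape, facet_a: str, facet_b: str) -> Axis:
    """Line through the mid-points of two facets of one bone."""
    a = facet_midpoint(shape, facet_a)
    b = facet_midpoint(shape, facet_b)
    if np.allclose(a, b):
        raise ValueError(f"coincident facet midpoints ({facet_a}, {facet_b})")
    return Axis(anchor=(a + b) / 2, direction=b - a)


def angle_between(axis1: Axis, axis2: Axis) -> float:
    """Angle in degrees, in [0, 180), between two canonically oriented axes.

    Exactly opposite directions cannot occur for two distally oriented
    axes; they indicate an orientation-flag error upstream and raise.
    """
    c = float(np.clip(axis1.direction @ axis2.direction, -1.0, 1.0))
    ang = float(np.degrees(np.arccos(c)))
    if ang >= 180.0 - 1e-9:
        raise ValueError("opposite axis orientations: upstream flag error")
    return ang


def lunate_axis(lunate: LandmarkedShape) -> Axis:
    """Lunate mid-plane axis: radius-facet midpoint → capitate-facet midpoint."""
    return facet_axis(lunate, "lunate_radius", "lunate_capitate")


def capitate_axis(capitate: LandmarkedShape) -> Axis:
    """Capitate long axis: lunate-facet midpoint → metacarpal-III-facet midpoint."""
    return facet_axis(capitate, "capitate_lunate", "capitate_mc3")


def scaphoid_axis(scaphoid: LandmarkedShape) -> Axis:
    """Scaphoid long axis: principal axis of the lateral contour."""
    return principal_axis(scaphoid)


# ---------------------------------------------------------------------------
# measurements


def sl_distance(scaphoid: LandmarkedShape, lunate: LandmarkedShape,
                view: View = View.NEUTRAL_AP_PA, age_years: float = 40.0,
                config: ThresholdConfig | None = None) -> MeasurementResult:
    """SL joint distance: mid-point to mid-point of the facing SL facets."""
    view = View(view)
    if not view.is_frontal:
        raise ValueError("SL distance is measured on AP/PA views")
    ms = facet_midpoint(scaphoid, "scaphoid_lunate")
    ml = facet_midpoint(lunate, "lunate_scaphoid")
    value = float(np.linalg.norm(ms - ml))
    return classify("sl_distance", value, view, age_years,
                    config or ThresholdConfig())


def sl_angle(scaphoid: LandmarkedShape, lunate: LandmarkedShape,
             view: View = View.LATERAL, age_years: float = 40.0,
             config: ThresholdConfig | None = None) -> MeasurementResult:
    view = View(view)
    if view != View.LATERAL:
        raise ValueError("SL angle is measured on the lateral view")
    value = angle_between(scaphoid_axis(scaphoid), lunate_axis(lunate))
    return classify("sl_angle", value, view, age_years,
                    config or ThresholdConfig())


def cl_angle(capitate: LandmarkedShape, lunate: LandmarkedShape,
             view: View = View.LATERAL, age_years: float = 40.0,
             config: ThresholdConfig | None = None) -> MeasurementResult:
    view = View(view)
    if view != View.LATERAL:
        raise ValueError("CL angle is measured on the lateral view")
    value = angle_between(capitate_axis(capitate), lunate_axis(lunate))
    return classify("cl_angle", value, view, age_years,
                    config or ThresholdConfig())


def _sl_distance_threshold(view: View, age_years: float,
                           config: ThresholdConfig) -> tuple[float, str]:
    if age_years <= config.pediatric_age_max:
        # ages 6-14 use per-age-band upper limits from the pediatric table
        for band, limit in config.pediatric_sl_table.items():
            lo, hi = (float(x) for x in band.split("-"))
            if lo <= age_years <= hi:
                return float(limit), f"pediatric band {band}: > {limit} mm"
        raise UnclassifiableError(
            f"no pediatric SL-distance table entry for age {age_years}")
    if view == View.ULNAR_DEVIATED_AP_PA:
        return (config.sl_distance_ulnar_mm,
                f"ulnar-deviated: > {config.sl_distance_ulnar_mm} mm")
    rule = f"neutral: > {config.sl_distance_neutral_mm} mm"
    if view == View.CLENCHED_FIST_AP_PA:
        rule += " (assumption: clenched-fist uses neutral threshold)"
    return config.sl_distance_neutral_mm, rule


def classify(name: str, value: float, view: View, age_years: float,
             config: ThresholdConfig) -> MeasurementResult:
    """Apply the view- and age-appropriate threshold rule.

    Abnormal means strictly *exceeding* the reference range: boundary
    values are normal (an SL distance of exactly 3.0 mm, an SL angle of
    exactly 30 or 60 degrees and a CL angle of exactly 30 degrees all
    classify as normal).
    """
    view = View(view)
    if name == "sl_distance":
        if not view.is_frontal:
            raise ValueError("SL distance requires an AP/PA view")
        thr, rule = _sl_distance_threshold(view, age_years, config)
        abnormal = value > thr
    elif name == "sl_angle":
        lo, hi = config.sl_angle_range_deg
        rule = f"normal in [{lo}, {hi}] deg"
        abnormal = value < lo or value > hi
    elif name == "cl_angle":
        rule = f"normal <= {config.cl_angle_max_deg} deg"
        abnormal = value > config.cl_angle_max_deg
    else:
        raise ValueError(f"unknown measurement '{name}'")
    return MeasurementResult(name=name, value=float(value), abnormal=bool(abnormal),
                             threshold_rule=rule, view=view, age_years=age_years)
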