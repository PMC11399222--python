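"""Parametric synthetic wrist phantom with known ground truth.

Generates AP/PA and lateral wrist geometries (per-bone contours plus
rasterised label masks) whose scapholunate (SL) gap, SL/CL angles and
carpal-arc interruption state are known exactly by construction, so every
downstream stage — contour extraction, shape-model fitting, measurement,
arc assessment — can be tested without clinical data.

The AP/PA carpus is laid out on concentric circular arcs around a common
centre, mirroring Gilula's three smooth carpal arcs: the proximal row
(scaphoid, lunate, triquetrum) occupies one annulus, the distal row
(capitate, hamate) a second, and each bone is a circular-annulus sector
whose side faces are straight cuts.  The two faces bounding the SL joint
are parallel segments separated by exactly ``sl_gap_mm``, so the facet
mid-point distance equals the requested gap analytically.  Interruption is
modelled as a proximal (larger-y) translation of the capitate — the
clinically observed mechanism of a capitate subluxating proximally into a
widened SL space — which produces a step-off in the distal arc.  A purely
widened SL gap with no proximal shift leaves the arcs aligned (only
lengthened) and is therefore a *non*-interrupted case.

The lateral view stacks radius → lunate → capitate → third metacarpal
base, with the capitate (and attached metacarpal) tilted by the requested
CL angle about the capitolunate joint and an elliptical scaphoid whose
major axis makes the requested SL angle with the lunate mid-plane axis.

Coordinates follow the image convention (x rightward, y downward, mm);
"proximal" is larger y.  All contours are counter-clockwise (positive
shoelace area in stored coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon as _ShPolygon

from .geometry import rotation_matrix, shoelace_area
from .mask_io import LABEL_TABLE, Bone, Contour, StudyMeta, View, write_contours, write_label_mask

#: Template canvas (mm); images span [0, CANVAS_MM] in x and y.
CANVAS_MM = 70.0

#: Proximal capitate/lunate translation above which the arcs are
#: considered interrupted (the generator's declared step threshold).
INTERRUPTION_STEP_MM = 1.0

_CANVAS_CENTRE = np.array([CANVAS_MM / 2, CANVAS_MM / 2])


class InfeasibleGeometryError(ValueError):
    """Requested parameters produce overlapping or invalid bones."""


class OutOfCanvasError(ValueError):
    """A contour extends beyond the raster canvas."""


@dataclass
class WristParams:
    """Ground-truth parameters of one synthetic wrist.

    ``interrupted`` may be left as None, in which case it is derived from
    ``subluxation_mm > INTERRUPTION_STEP_MM``; an explicitly inconsistent
    value raises.
    """

    sl_gap_mm: float = 2.0
    sl_angle_deg: float = 47.0
    cl_angle_deg: float = 10.0
    subluxation_mm: float = 0.0
    interrupted: bool | None = None
    global_scale: float = 1.0
    rotation_deg: float = 0.0
    noise_sd_mm: float = 0.0
    seed: int = 0
    age_years: float = 40.0

    def __post_init__(self):
        if self.sl_gap_mm < 0:
            raise ValueError("sl_gap_mm must be >= 0")
        if not (0.0 <= self.sl_angle_deg <= 120.0):
            raise ValueError("sl_angle_deg must be in [0, 120]")
        if not (-30.0 <= self.cl_angle_deg <= 90.0):
            raise ValueError("cl_angle_deg must be in [-30, 90]")
        if self.subluxation_mm < 0:
            raise ValueError("subluxation_mm must be >= 0")
        if not (self.global_scale > 0):
            raise ValueError("global_scale must be > 0")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        derived = self.subluxation_mm > INTERRUPTION_STEP_MM
        if self.interrupted is None:
            self.interrupted = derived
        elif bool(self.interrupted) != derived:
            raise ValueError(
                f"interrupted={self.interrupted} inconsistent with "
                f"subluxation_mm={self.subluxation_mm} (step threshold "
                f"{INTERRUPTION_STEP_MM} mm)")


@dataclass
class SyntheticCase:
    params: WristParams
    contours_ap: dict[Bone, Contour]
    contours_lat: dict[Bone, Contour]
    truth: dict
    truth_facets: dict
    label_mask_ap: np.ndarray | None = None
    label_mask_lat: np.ndarray | None = None
    spacing_mm_per_px: float | None = None

    def meta(self, view: View, study_id: str = "") -> StudyMeta:
        return StudyMeta(spacing_mm_per_px=self.spacing_mm_per_px,
                         view=view, age_years=self.params.age_years,
                         study_id=study_id)


# ---------------------------------------------------------------------------
# primitive bone builders


def _dir(phi):
    """Unit vector at angle ``phi`` (rad) from the downward (+y) axis."""
    return np.array([np.sin(phi), np.cos(phi)])


def _tangent(phi):
    return np.array([np.cos(phi), -np.sin(phi)])


def _sector_bone(centre, r_in, r_out,
                 phi_left, s_left, phi_right, s_right,
                 n_arc=22, n_side=12):
    """Annulus-sector bone with straight cut side faces.

    A side face at ``(phi, s)`` is the straight segment parallel to the
    radial direction at gap-centre angle ``phi``, offset tangentially by
    ``s`` mm; its endpoints lie exactly on the two circles.  Returns the
    closed CCW contour and generic facet index ranges
    (distal_surface / right / proximal_surface / left, half-open).
    """
    centre = np.asarray(centre, dtype=float)

    def arc(r, p0, s0, p1, s1, m):
        a0 = p0 + np.arcsin(s0 / r)
        a1 = p1 + np.arcsin(s1 / r)
        phis = np.linspace(a0, a1, m)
        return centre + r * np.column_stack([np.sin(phis), np.cos(phis)])

    def face(phi, s, t0, t1, m):
        u, w = _dir(phi), _tangent(phi)
        t = np.linspace(t0, t1, m)
        return centre + t[:, None] * u[None, :] + s * w[None, :]

    t_in_r = np.sqrt(r_in ** 2 - s_right ** 2)
    t_out_r = np.sqrt(r_out ** 2 - s_right ** 2)
    t_in_l = np.sqrt(r_in ** 2 - s_left ** 2)
    t_out_l = np.sqrt(r_out ** 2 - s_left ** 2)

    faces = [
        arc(r_in, phi_left, s_left, phi_right, s_right, n_arc),      # distal
        face(phi_right, s_right, t_in_r, t_out_r, n_side),           # right
        arc(r_out, phi_right, s_right, phi_left, s_left, n_arc),     # proximal
        face(phi_left, s_left, t_out_l, t_in_l, n_side),             # left
    ]
    return _assemble(faces, ["distal_surface", "right", "proximal_surface", "left"])


def _rect_bone(centre, w, h, tilt_deg=0.0, pivot=None, n_long=18, n_side=15):
    """Rectangle bone (top = distal face), optionally tilted about ``pivot``."""
    cx, cy = centre
    tl = np.array([cx - w / 2, cy - h / 2])
    tr = np.array([cx + w / 2, cy - h / 2])
    br = np.array([cx + w / 2, cy + h / 2])
    bl = np.array([cx - w / 2, cy + h / 2])

    def seg(a, b, m):
        t = np.linspace(0, 1, m)
        return a[None, :] + t[:, None] * (b - a)[None, :]

    faces = [
        seg(tl, tr, n_long),   # distal (top)
        seg(tr, br, n_side),   # right
        seg(br, bl, n_long),   # proximal (bottom)
        seg(bl, tl, n_side),   # left
    ]
    pts, facets = _assemble(faces, ["distal_surface", "right", "proximal_surface", "left"])
    if tilt_deg:
        pivot = np.asarray(pivot if pivot is not None else centre, dtype=float)
        pts = (pts - pivot) @ rotation_matrix(tilt_deg).T + pivot
    return pts, facets


def _capsule_bone(pivot, w, shaft_h, tilt_deg=0.0, n_long=18, n_side=12, n_cap=22):
    """Rect bone with a semicircular proximal cap centred on ``pivot``.

    Used for the lateral capitate: the cap models the rounded capitate
    head articulating in the lunate cup, so tilting the bone about the
    pivot never changes its proximal footprint.  The proximal facet is
    the cap; its arc-length midpoint lies on the tilted long axis.
    """
    pivot = np.asarray(pivot, dtype=float)
    r = w / 2.0

    def seg(a, b, m):
        t = np.linspace(0, 1, m)
        return a[None, :] + t[:, None] * (np.asarray(b) - np.asarray(a))[None, :]

    tl, tr = np.array([-r, -shaft_h]), np.array([r, -shaft_h])
    beta = np.linspace(0.0, np.pi, n_cap)
    cap = np.column_stack([r * np.cos(beta), r * np.sin(beta)])
    faces = [
        seg(tl, tr, n_long),                  # distal (top)
        seg(tr, np.array([r, 0.0]), n_side),  # right
        cap,                                  # proximal cap
        seg(np.array([-r, 0.0]), tl, n_side),  # left
    ]
    pts, facets = _assemble(faces, ["distal_surface", "right", "proximal_surface", "left"])
    R = rotation_matrix(tilt_deg)
    return pts @ R.T + pivot, facets


def _ellipse_bone(centre, a, b, tilt_deg, n=64):
    """Elliptical bone; major axis tilted ``tilt_deg`` from the distal (−y) axis."""
    centre = np.asarray(centre, dtype=float)
    R = rotation_matrix(tilt_deg)
    e1, e2 = R @ np.array([0.0, -1.0]), R @ np.array([1.0, 0.0])
    tau = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = centre + np.outer(a * np.cos(tau), e1) + np.outer(b * np.sin(tau), e2)
    return pts, {}


def _assemble(faces, names):
    """Concatenate face polylines (shared corners deduplicated) and return
    the closed contour with half-open facet ranges.

    The last face's closing corner is vertex 0 again, so its range wraps:
    a range (start, stop) with stop > n indexes modulo n.
    """
    pts, facets, start = [], {}, 0
    for f, name in zip(faces, names):
        block = f[:-1]
        facets[name] = (start, start + len(f))
        pts.append(block)
        start += len(block)
    contour = np.vstack(pts)
    if shoelace_area(contour) <= 0:
        raise AssertionError("template construction must be CCW")
    return contour, facets


# ---------------------------------------------------------------------------
# view assembly

_D = np.deg2rad


def _build_ap(sl_gap: float, subluxation: float):
    """Template-frame AP/PA geometry; returns (contours, facets) dicts."""
    C = np.array([35.0, 6.0])
    bones: dict[Bone, np.ndarray] = {}
    facets: dict[Bone, dict] = {}

    phi_sl, phi_lt, phi_ch = _D(-9.0), _D(12.0), _D(9.0)
    half_sl, half_small = sl_gap / 2.0, 0.75

    def add(bone, pts, fac, rename=None, aliases=None):
        fac = dict(fac)
        if rename:
            for old, new in rename.items():
                fac[new] = fac.pop(old)
        if aliases:
            for new, src in aliases.items():
                fac[new] = fac[src]
        bones[bone] = pts
        facets[bone] = fac

    pts, fac = _sector_bone(C, 23.0, 34.0, _D(-38.0), 0.0, phi_sl, -half_sl)
    add(Bone.SCAPHOID, pts, fac, rename={"right": "scaphoid_lunate"})

    pts, fac = _sector_bone(C, 23.0, 34.0, phi_sl, +half_sl, phi_lt, -half_small)
    add(Bone.LUNATE, pts, fac, rename={"left": "lunate_scaphoid"},
        aliases={"lunate_radius": "proximal_surface",
                 "lunate_capitate": "distal_surface"})

    pts, fac = _sector_bone(C, 23.0, 34.0, phi_lt, +half_small, _D(34.0), 0.0)
    add(Bone.TRIQUETRUM, pts, fac)

    pts, fac = _sector_bone(C, 6.5, 19.0, _D(-14.0), 0.0, phi_ch, -half_small)
    pts = pts + np.array([0.0, subluxation])
    add(Bone.CAPITATE, pts, fac,
        aliases={"capitate_lunate": "proximal_surface",
                 "capitate_mc3": "distal_surface"})

    pts, fac = _sector_bone(C, 11.0, 19.0, phi_ch, +half_small, _D(32.0), 0.0)
    add(Bone.HAMATE, pts, fac)

    pts, fac = _rect_bone((34.7, 7.8), 9.0, 6.0)
    add(Bone.METACARPAL3, pts, fac)

    pts, fac = _rect_bone((32.0, 50.0), 36.0, 12.0)
    add(Bone.RADIUS, pts, fac)
    return bones, facets


def _build_lateral(sl_angle: float, cl_angle: float):
    """Template-frame lateral geometry; returns (contours, facets) dicts."""
    bones: dict[Bone, np.ndarray] = {}
    facets: dict[Bone, dict] = {}

    pts, fac = _rect_bone((35.0, 55.5), 30.0, 12.0)
    bones[Bone.RADIUS], facets[Bone.RADIUS] = pts, fac

    pts, fac = _rect_bone((35.0, 43.5), 14.0, 9.0)
    fac = dict(fac)
    fac["lunate_radius"] = fac["proximal_surface"]
    fac["lunate_capitate"] = fac["distal_surface"]
    bones[Bone.LUNATE], facets[Bone.LUNATE] = pts, fac

    cap_w, shaft_h, cap_gap = 9.0, 17.5, 1.4
    # pivot = centre of the capitate head; head radius w/2 reaches to
    # cap_gap above the lunate's distal face for every tilt
    pivot = np.array([35.0, 48.0 - 9.0 - cap_gap - cap_w / 2])
    pts, fac = _capsule_bone(pivot, cap_w, shaft_h, tilt_deg=cl_angle)
    fac = dict(fac)
    fac["capitate_lunate"] = fac["proximal_surface"]
    fac["capitate_mc3"] = fac["distal_surface"]
    bones[Bone.CAPITATE], facets[Bone.CAPITATE] = pts, fac

    axis = rotation_matrix(cl_angle) @ np.array([0.0, -1.0])
    mc3_c = pivot + (shaft_h + 1.5 + 4.5) * axis
    pts, fac = _rect_bone(mc3_c, 8.0, 9.0, tilt_deg=cl_angle, pivot=mc3_c)
    bones[Bone.METACARPAL3], facets[Bone.METACARPAL3] = pts, fac

    pts, fac = _ellipse_bone((20.5, 34.5), 8.0, 3.5, sl_angle)
    bones[Bone.SCAPHOID], facets[Bone.SCAPHOID] = pts, fac
    return bones, facets


def _contour_jitter(rng, pts: np.ndarray, sd_mm: float) -> np.ndarray:
    """Spatially correlated boundary jitter with marginal SD ``sd_mm``.

    Vertices are displaced by a smooth random vector field over the
    plane (random Fourier features with ~2 mm correlation length), as
    segmentation errors are smooth along a boundary.  The field's
    gradient is far below 1 at these amplitudes, so the perturbation is
    injective and cannot self-intersect even densely sampled contours.
    """
    n_feat, corr_mm = 24, 2.0
    theta = rng.uniform(0, 2 * np.pi, n_feat)
    kvec = (rng.uniform(0, np.pi / corr_mm, n_feat)[:, None]
            * np.column_stack([np.cos(theta), np.sin(theta)]))
    phase = rng.uniform(0, 2 * np.pi, n_feat)
    w = rng.normal(0.0, 1.0, (n_feat, 2))
    basis = np.cos(pts @ kvec.T + phase)          # (n_points, n_feat)
    return sd_mm * np.sqrt(2.0 / n_feat) * (basis @ w)


def _check_feasible(bones: dict[Bone, np.ndarray], view: str):
    polys = {}
    for bone, pts in bones.items():
        poly = _ShPolygon(pts)
        if not poly.is_valid:
            raise InfeasibleGeometryError(
                f"{view}: {bone.value} contour is self-intersecting")
        polys[bone] = poly
    items = list(polys.items())
    for i, (b1, p1) in enumerate(items):
        for b2, p2 in items[i + 1:]:
            if p1.intersection(p2).area > 1e-6:
                raise InfeasibleGeometryError(
                    f"{view}: bones overlap ({b1.value}, {b2.value})")


# ---------------------------------------------------------------------------
# rasterisation


def default_image_size(spacing_mm_per_px: float) -> tuple[int, int]:
    n = int(round(CANVAS_MM / spacing_mm_per_px)) + 1
    return (n, n)


def rasterize(contours: dict[Bone, Contour | np.ndarray],
              spacing_mm_per_px: float,
              image_size: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterise contours to an integer label image.

    Labels follow :data:`carpalkit.mask_io.LABEL_TABLE`, background is 0.
    Fill convention: a pixel belongs to a bone iff its centre lies inside
    the polygon; pixel (row i, col j) has centre (x, y) = (j, i)·spacing.
    """
    if not (spacing_mm_per_px > 0):
        raise ValueError("spacing must be > 0")
    if image_size is None:
        image_size = default_image_size(spacing_mm_per_px)
    h, w = image_size
    img = np.zeros((h, w), dtype=np.uint8)
    xmax, ymax = (w - 1) * spacing_mm_per_px, (h - 1) * spacing_mm_per_px
    for bone in LABEL_TABLE:
        if bone not in contours:
            continue
        obj = contours[bone]
        pts = obj.points if isinstance(obj, Contour) else np.asarray(obj, float)
        if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                or pts[:, 0].max() > xmax or pts[:, 1].max() > ymax):
            raise OutOfCanvasError(f"{bone.value} contour exceeds the canvas")
        j0 = max(int(np.floor(pts[:, 0].min() / spacing_mm_per_px)) - 1, 0)
        j1 = min(int(np.ceil(pts[:, 0].max() / spacing_mm_per_px)) + 1, w - 1)
        i0 = max(int(np.floor(pts[:, 1].min() / spacing_mm_per_px)) - 1, 0)
        i1 = min(int(np.ceil(pts[:, 1].max() / spacing_mm_per_px)) + 1, h - 1)
        jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
        centres = np.column_stack([jj.ravel(), ii.ravel()]) * spacing_mm_per_px
        # Path with closed=True treats the final vertex as the CLOSEPOLY
        # placeholder, so the first vertex must be appended explicitly
        path = _MplPath(np.vstack([pts, pts[:1]]), closed=True)
        inside = path.contains_points(centres)
        sub = img[i0:i1 + 1, j0:j1 + 1].ravel()
        sub[inside] = LABEL_TABLE[bone]
        img[i0:i1 + 1, j0:j1 + 1] = sub.reshape(ii.shape)
    return img


# ---------------------------------------------------------------------------
# case and cohort generation


def generate_case(params: WristParams, spacing_mm_per_px: float = 0.2,
                  with_masks: bool = True) -> SyntheticCase:
    """Generate one synthetic wrist (both views) with exact ground truth.

    Deterministic for a fixed seed.  The SL gap and subluxation are
    applied in absolute mm regardless of ``global_scale`` (bone size
    varies between patients; joint-space pathology is measured in mm), so
    analytic measurement of the generated geometry returns the params'
    values exactly before any rasterisation.
    """
    if not (spacing_mm_per_px > 0):
        raise ValueError("spacing must be > 0")
    s = params.global_scale
    ap_bones, ap_facets = _build_ap(params.sl_gap_mm / s,
                                    params.subluxation_mm / s)
    lat_bones, lat_facets = _build_lateral(params.sl_angle_deg,
                                           params.cl_angle_deg)

    R = rotation_matrix(params.rotation_deg)
    rng = np.random.default_rng(params.seed)
    for bones in (ap_bones, lat_bones):
        for bone in sorted(bones, key=lambda b: b.value):
            pts = bones[bone]
            pts = (pts - _CANVAS_CENTRE) @ (s * R).T + _CANVAS_CENTRE
            if params.noise_sd_mm > 0:
                pts = pts + _contour_jitter(rng, pts, params.noise_sd_mm)
            bones[bone] = pts

    _check_feasible(ap_bones, "ap")
    _check_feasible(lat_bones, "lateral")

    contours_ap = {b: Contour(bone=b, points=p) for b, p in ap_bones.items()}
    contours_lat = {b: Contour(bone=b, points=p) for b, p in lat_bones.items()}

    truth = {
        "sl_distance_mm": params.sl_gap_mm,
        "sl_angle_deg": abs(params.sl_angle_deg),
        "cl_angle_deg": abs(params.cl_angle_deg),
        "subluxation_mm": params.subluxation_mm,
        "interrupted": bool(params.interrupted),
    }
    truth_facets = {
        "ap": {b.value: {k: list(v) for k, v in f.items()}
               for b, f in ap_facets.items()},
        "lateral": {b.value: {k: list(v) for k, v in f.items()}
                    for b, f in lat_facets.items()},
    }
    case = SyntheticCase(params=params, contours_ap=contours_ap,
                         contours_lat=contours_lat, truth=truth,
                         truth_facets=truth_facets,
                         spacing_mm_per_px=spacing_mm_per_px)
    if with_masks:
        case.label_mask_ap = rasterize(contours_ap, spacing_mm_per_px)
        case.label_mask_lat = rasterize(contours_lat, spacing_mm_per_px)
    return case


#: Default cohort sampling ranges: uniform (low, high) per parameter.
DEFAULT_DISTRIBUTIONS = {
    "sl_gap_mm": (1.2, 2.8),
    "sl_gap_mm_widened": (3.5, 5.0),
    "sl_angle_deg": (35.0, 60.0),
    "cl_angle_deg": (2.0, 25.0),
    "rotation_deg": (-8.0, 8.0),
    "global_scale": (0.92, 1.08),
    # correlated contour jitter emulating segmentation error
    # (about half a pixel at the default 0.2 mm/px spacing)
    "noise_sd_mm": 0.1,
    "subluxation_mm_interrupted": 3.0,
}


def generate_cohort(n: int, param_distributions: dict | None = None,
                    seed: int = 0, spacing_mm_per_px: float = 0.2,
                    interrupted_frac: float = 0.0,
                    widened_frac: float = 0.0,
                    with_masks: bool = True) -> list[SyntheticCase]:
    """Generate a reproducible cohort of synthetic wrists.

    ``round(n * interrupted_frac)`` cases receive the interrupted
    subluxation; ``round(n * widened_frac)`` of the remaining normals get
    a widened-but-aligned SL gap (lengthened arcs, *not* an interruption).
    Case order is a seed-determined permutation of the status assignment.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    dist = dict(DEFAULT_DISTRIBUTIONS)
    if param_distributions:
        dist.update(param_distributions)
    rng = np.random.default_rng(seed)

    n_int = int(round(n * interrupted_frac))
    n_wid = min(int(round(n * widened_frac)), n - n_int)
    status = np.array(["interrupted"] * n_int + ["widened"] * n_wid
                      + ["normal"] * (n - n_int - n_wid))
    status = status[rng.permutation(n)]

    def draw(key):
        v = dist[key]
        return float(rng.uniform(*v)) if isinstance(v, (tuple, list)) else float(v)

    cases = []
    for st in status:
        gap_key = "sl_gap_mm_widened" if st == "widened" else "sl_gap_mm"
        sub = draw("subluxation_mm_interrupted") if st == "interrupted" else 0.0
        params = WristParams(
            sl_gap_mm=draw(gap_key),
            sl_angle_deg=draw("sl_angle_deg"),
            cl_angle_deg=draw("cl_angle_deg"),
            subluxation_mm=sub,
            global_scale=draw("global_scale"),
            rotation_deg=draw("rotation_deg"),
            noise_sd_mm=draw("noise_sd_mm"),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        cases.append(generate_case(params, spacing_mm_per_px,
                                   with_masks=with_masks))
    return cases


def save_cohort(cases: list[SyntheticCase], out_dir) -> list[str]:
    """Write a cohort to disk: per case an AP and lateral label-mask PNG,
    JSON sidecars with the ground truth, and contour JSON files."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    for i, case in enumerate(cases):
        cid = f"case_{i:04d}"
        cdir = out_dir / cid
        cdir.mkdir(exist_ok=True)
        extra = {"truth": case.truth, "truth_facets": case.truth_facets}
        if case.label_mask_ap is None:
            raise ValueError("cohort was generated without masks")
        write_label_mask(cdir / "ap_mask.png", case.label_mask_ap,
                         case.meta(View.NEUTRAL_AP_PA, cid), extra)
        write_label_mask(cdir / "lateral_mask.png", case.label_mask_lat,
                         case.meta(View.LATERAL, cid), extra)
        write_contours(cdir / "ap_contours.json", case.contours_ap)
        write_contours(cdir / "lateral_contours.json", case.contours_lat)
        ids.append(cid)
    return ids
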