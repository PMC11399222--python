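"""Gilula carpal arcs: construction, normal-shape reconstruction and
interruption detection.

On a neutral AP/PA view the aligned carpus shows three smooth arcs: the
proximal arc along the proximal articular surfaces of scaphoid, lunate
and triquetrum; the middle arc along their distal surfaces; and the
distal arc along the proximal surfaces of capitate and hamate.  Each arc
is represented as an open polyline of 100 arc-length-uniform points
ordered radial → ulnar.

Interruptions are detected by comparing each observed arc with its
*hypothetical normal* reconstruction: the arc is aligned into the frame
of a point distribution model trained on non-interrupted arcs, projected
onto the mode subspace with coefficients clamped to ±3σ, and mapped back.
Per-point z-scores are the model-frame residual magnitudes divided by the
per-landmark residual scale of the training set; the disruption score is
the fraction of all arc points with z at or above ``z_crit``, and a study
is flagged when the score reaches the operating threshold (0.11 at the
default operating point).  Because the training set includes widened but
aligned wrists, a dissociation that only *lengthens* the arcs stays
inside the mode subspace and scores low — only true step-offs are
interruptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import resample_polyline
from .mask_io import Bone, View
from .shape_model import LandmarkedShape, PointDistributionModel

ARC_POINTS = 100
ARC_NAMES = ("proximal", "middle", "distal")

#: bones and facet per arc, in radial → ulnar order
ARC_DEFINITIONS = {
    "proximal": [(Bone.SCAPHOID, "proximal_surface"),
                 (Bone.LUNATE, "proximal_surface"),
                 (Bone.TRIQUETRUM, "proximal_surface")],
    "middle": [(Bone.SCAPHOID, "distal_surface"),
               (Bone.LUNATE, "distal_surface"),
               (Bone.TRIQUETRUM, "distal_surface")],
    "distal": [(Bone.CAPITATE, "proximal_surface"),
               (Bone.HAMATE, "proximal_surface")],
}


@dataclass
class ArcSet:
    """The three carpal arcs (100 points each); an arc that could not be
    built (missing bone) is None."""

    proximal: np.ndarray | None = None
    middle: np.ndarray | None = None
    distal: np.ndarray | None = None
    view: View = View.NEUTRAL_AP_PA

    def __post_init__(self):
        self.view = View(self.view)
        for name in ARC_NAMES:
            arc = getattr(self, name)
            if arc is not None:
                arc = np.asarray(arc, dtype=float)
                if arc.shape != (ARC_POINTS, 2):
                    raise ValueError(
                        f"arc '{name}' must have shape ({ARC_POINTS}, 2)")
                setattr(self, name, arc)

    def items(self):
        for name in ARC_NAMES:
            arc = getattr(self, name)
            if arc is not None:
                yield name, arc

    @property
    def available(self) -> list[str]:
        return [name for name, _ in self.items()]


@dataclass
class ArcAssessment:
    observed: ArcSet
    reconstructed: ArcSet
    displacement: dict[str, np.ndarray]   # observed - reconstructed, mm
    zscores: dict[str, np.ndarray]
    disruption_score: float
    detected: bool
    threshold: float
    z_crit: float
    markers: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _oriented_facet(shape: LandmarkedShape, facet: str) -> np.ndarray:
    """Facet polyline oriented radial → ulnar (increasing x; the most
    radial endpoint — ties toward smaller x — comes first)."""
    pts = shape.facet_polyline(facet)
    if pts[0, 0] > pts[-1, 0]:
        pts = pts[::-1]
    return pts


def build_arcs(shapes: dict[Bone, LandmarkedShape],
               view: View = View.NEUTRAL_AP_PA) -> ArcSet:
    """Concatenate the per-bone articular facets into the three arcs and
    resample each to 100 arc-length-uniform points.

    Arcs whose bones are missing come back as None rather than raising.
    """
    view = View(view)
    if view != View.NEUTRAL_AP_PA:
        raise ValueError("carpal arcs are defined on the neutral AP/PA view")
    arcs = {}
    for name, parts in ARC_DEFINITIONS.items():
        if any(bone not in shapes for bone, _ in parts):
            arcs[name] = None
            continue
        segments = [_oriented_facet(shapes[bone], facet) for bone, facet in parts]
        concat = np.vstack(segments)
        arcs[name] = resample_polyline(concat, ARC_POINTS)
    return ArcSet(view=view, **arcs)


# ---------------------------------------------------------------------------
# detector


class ArcInterruptionDetector(BaseEstimator):
    """PDM-based detector of carpal arc interruptions.

    Parameters
    ----------
    z_crit : float
        Per-point z-score at or above which a point counts as deviating.
    threshold : float
        Operating threshold on the disruption score (default 0.11).
    variance_target, residual_floor_mm, clamp_sd :
        Passed to the per-arc :class:`PointDistributionModel`.

    Fitted attributes
    -----------------
    models_ : dict arc-name → PointDistributionModel (one per arc).
    n_training_ : number of training arc sets.
    """

    def __init__(self, z_crit: float = 2.0, threshold: float = 0.11,
                 variance_target: float = 0.95,
                 residual_floor_mm: float = 0.05, clamp_sd: float = 3.0):
        self.z_crit = z_crit
        self.threshold = threshold
        self.variance_target = variance_target
        self.residual_floor_mm = residual_floor_mm
        self.clamp_sd = clamp_sd

    def fit(self, arcsets: list[ArcSet], y=None):
        """Train one PDM per arc on non-interrupted arc sets (>= 10)."""
        if len(arcsets) < 10:
            raise ValueError("need at least 10 non-interrupted arc sets")
        self.models_ = {}
        for name in ARC_NAMES:
            stack = [getattr(a, name) for a in arcsets
                     if getattr(a, name) is not None]
            if len(stack) < 10:
                raise ValueError(f"fewer than 10 training arcs for '{name}'")
            model = PointDistributionModel(
                variance_target=self.variance_target,
                residual_floor_mm=self.residual_floor_mm,
                clamp_sd=self.clamp_sd)
            model.fit(np.stack(stack))
            self.models_[name] = model
        self.n_training_ = len(arcsets)
        return self

    # -- assessment ---------------------------------------------------------

    def assess(self, arcset: ArcSet) -> ArcAssessment:
        recon = {name: None for name in ARC_NAMES}
        displacement, zscores, markers = {}, {}, {}
        all_z = []
        for name, observed in arcset.items():
            proj = self.models_[name].decompose(observed)
            model = self.models_[name]
            res = proj.aligned - proj.reconstruction_model
            z = np.hypot(res[:, 0], res[:, 1]) / model.residual_sd_
            recon[name] = proj.reconstruction
            displacement[name] = observed - proj.reconstruction
            zscores[name] = z
            markers[name] = _runs(z >= self.z_crit)
            all_z.append(z)
        if not all_z:
            raise ValueError("arc set has no available arcs")
        score = disruption_score(all_z, self.z_crit)
        return ArcAssessment(
            observed=arcset,
            reconstructed=ArcSet(view=arcset.view, **recon),
            displacement=displacement, zscores=zscores,
            disruption_score=score,
            detected=score >= self.threshold,
            threshold=self.threshold, z_crit=self.z_crit, markers=markers)

    def decision_function(self, arcsets: list[ArcSet]) -> np.ndarray:
        return np.array([self.assess(a).disruption_score for a in arcsets])

    def predict(self, arcsets: list[ArcSet]) -> np.ndarray:
        return self.decision_function(arcsets) >= self.threshold

    def reconstruct_normal(self, arcset: ArcSet) -> ArcSet:
        """The closest plausible-normal arc set, in the image frame."""
        recon = {name: self.models_[name].decompose(obs).reconstruction
                 for name, obs in arcset.items()}
        return ArcSet(view=arcset.view, **recon)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [(int(g[0]), int(g[-1]) + 1) for g in np.split(idx, splits)]


# ---------------------------------------------------------------------------
# functional wrappers


def train_arc_pdm(arcsets: list[ArcSet], variance_target: float = 0.95,
                  **kwargs) -> ArcInterruptionDetector:
    """Train the per-arc PDMs; returns the fitted detector."""
    return ArcInterruptionDetector(variance_target=variance_target,
                                   **kwargs).fit(arcsets)


def reconstruct_normal(observed: ArcSet,
                       detector: ArcInterruptionDetector) -> ArcSet:
    return detector.reconstruct_normal(observed)


def arc_zscores(observed: ArcSet,
                detector: ArcInterruptionDetector) -> dict[str, np.ndarray]:
    return detector.assess(observed).zscores


def disruption_score(zscores, z_crit: float = 2.0) -> float:
    """Fraction of all arc points with z >= z_crit (in [0, 1])."""
    if not (z_crit > 0):
        raise ValueError("z_crit must be > 0")
    z = np.concatenate([np.ravel(a) for a in zscores])
    return float(np.mean(z >= z_crit))


def detect_interruption(assessment: ArcAssessment,
                        threshold: float | None = None):
    """Re-evaluate detection at a (possibly different) threshold."""
    thr = assessment.threshold if threshold is None else threshold
    return assessment.disruption_score >= thr, assessment.markers


# ---------------------------------------------------------------------------
# heat-map rendering


def render_heatmap(assessment: ArcAssessment, background: np.ndarray,
                   spacing_mm_per_px: float, z_max: float = 4.0) -> np.ndarray:
    """Overlay the arc heat map on a background image.

    Each arc is drawn as 100 colour-coded points (warm = high z) with
    tail segments showing the displacement vectors back to the
    reconstructed normal arc, plus a z colour scale.  The returned RGB
    array has exactly the background's height and width.
    """
    import matplotlib
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    bg = np.asarray(background)
    h, w = bg.shape[:2]
    fig = Figure(figsize=(w / 100.0, h / 100.0), dpi=100)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_axis_off()
    ax.imshow(bg, cmap="gray", interpolation="nearest",
              extent=(-0.5 * spacing_mm_per_px,
                      (w - 0.5) * spacing_mm_per_px,
                      (h - 0.5) * spacing_mm_per_px,
                      -0.5 * spacing_mm_per_px))
    cmap = matplotlib.colormaps["turbo"]
    norm = matplotlib.colors.Normalize(vmin=0.0, vmax=z_max)
    for name, obs in assessment.observed.items():
        recon = getattr(assessment.reconstructed, name)
        for p, q in zip(obs, recon):
            ax.plot([p[0], q[0]], [p[1], q[1]], color="white",
                    linewidth=0.6, alpha=0.8, zorder=2)
        ax.scatter(obs[:, 0], obs[:, 1], c=assessment.zscores[name],
                   cmap=cmap, norm=norm, s=6, zorder=3, linewidths=0)
    cax = fig.add_axes([0.92, 0.08, 0.02, 0.3])
    matplotlib.colorbar.ColorbarBase(cax, cmap=cmap, norm=norm)
    cax.set_title("z", fontsize=8)
    canvas.draw()
    rgba = np.asarray(canvas.buffer_rgba())
    return rgba[:h, :w, :3].copy()
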