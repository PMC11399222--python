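"""Statistical shape machinery: Procrustes alignment, point distribution
models (PDMs), template fitting to contours, and facet-label transfer.

A PDM is a PCA model of corresponding 2-D landmark configurations after
generalized Procrustes alignment.  Reconstruction constrained to the mode
subspace (with coefficients clamped to ±3σ per mode) yields the closest
*plausible normal* shape — the device used both for locating articular
facet joint surfaces on a new contour and for reconstructing the
hypothetical non-interrupted carpal arcs.

The model frame is rescaled so the mean shape has the average training
centroid size: model-frame distances are therefore millimetres (of an
average-sized wrist), which keeps residual standard deviations and
z-scores physically interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import (
    arclength_midpoint,
    cumulative_arclength,
    facet_indices,
    project_points_to_polyline,
    resample_polyline,
)
from .mask_io import Bone, Contour


class DegenerateShapeError(ValueError):
    """All-coincident or otherwise unusable landmark configuration."""


@dataclass
class LandmarkedShape:
    """Ordered landmarks of one bone with named articular facet ranges.

    Facet ranges are half-open ``(start, stop)`` on the closed landmark
    loop; ``stop`` may exceed ``n`` to wrap past the start vertex.
    """

    bone: Bone
    landmarks: np.ndarray
    facets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.bone = Bone(self.bone)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        n = len(self.landmarks)
        for name, rng in self.facets.items():
            facet_indices(rng, n)  # validates

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    def facet_polyline(self, facet_name: str) -> np.ndarray:
        if facet_name not in self.facets:
            raise KeyError(f"{self.bone.value} has no facet "
                           f"'{facet_name}' (has: {sorted(self.facets)})")
        idx = facet_indices(self.facets[facet_name], self.n_landmarks)
        return self.landmarks[idx]


def facet_midpoint(shape: LandmarkedShape, facet_name: str) -> np.ndarray:
    """Point at half the cumulative arc length of the facet's polyline."""
    return arclength_midpoint(shape.facet_polyline(facet_name))


# ---------------------------------------------------------------------------
# similarity transforms


@dataclass
class SimilarityTransform:
    """x ↦ scale · R x + t  (rotation only, no reflection)."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
        )

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(1.0, np.eye(2), np.zeros(2))


def centroid_size(shape: np.ndarray) -> float:
    shape = np.asarray(shape, dtype=float)
    return float(np.sqrt(np.sum((shape - shape.mean(axis=0)) ** 2)))


def fit_similarity(source: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity (scale, rotation, translation) mapping
    ``source`` onto ``target`` (no reflection)."""
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    A, B = src - mu_s, dst - mu_d
    ssq = float(np.sum(A * A))
    if ssq <= 0:
        raise DegenerateShapeError("source shape has zero centroid size")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    s = float(np.trace(np.diag(S) @ D)) / ssq
    if s <= 0:
        s = 1e-12
    t = mu_d - s * (R @ mu_s)
    return SimilarityTransform(scale=s, rotation=R, translation=t)


def procrustes_align(shapes, tol: float = 1e-10, max_iter: int = 100):
    """Generalized Procrustes alignment of equally-sized landmark sets.

    Returns ``(aligned, transforms, mean)``: the aligned shapes, the
    per-shape similarity transforms mapping the *original* shape into the
    common frame, and the consensus mean (centred at the origin with unit
    centroid size).
    """
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 3 or X.shape[2] != 2:
        raise ValueError("expected shapes of shape (m, n, 2)")
    m, n, _ = X.shape
    if m < 2 or n < 3:
        raise ValueError("need >= 2 shapes with >= 3 landmarks")
    for i in range(m):
        if centroid_size(X[i]) <= 0:
            raise DegenerateShapeError(f"shape {i} is degenerate")

    mean = X[0] - X[0].mean(axis=0)
    mean = mean / centroid_size(mean)
    aligned = X.copy()
    transforms = [SimilarityTransform.identity()] * m
    for _ in range(max_iter):
        transforms = [fit_similarity(X[i], mean) for i in range(m)]
        aligned = np.stack([transforms[i].apply(X[i]) for i in range(m)])
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        size = centroid_size(new_mean)
        if size <= 0:
            raise DegenerateShapeError("degenerate consensus mean")
        new_mean = new_mean / size
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    transforms = [fit_similarity(X[i], mean) for i in range(m)]
    aligned = np.stack([transforms[i].apply(X[i]) for i in range(m)])
    return aligned, transforms, mean


# ---------------------------------------------------------------------------
# the PDM estimator


@dataclass
class ProjectionResult:
    """Decomposition of one shape against a PDM."""

    coefficients: np.ndarray         # clamped mode coefficients
    aligned: np.ndarray              # input mapped into the model frame
    reconstruction_model: np.ndarray  # plausible-normal shape, model frame
    reconstruction: np.ndarray       # plausible-normal shape, input frame
    transform: SimilarityTransform   # input frame -> model frame


class PointDistributionModel(BaseEstimator, TransformerMixin):
    """PCA point distribution model over Procrustes-aligned landmarks.

    Parameters
    ----------
    variance_target : float in (0, 1]
        Smallest number of modes whose cumulative explained variance
        reaches this fraction is retained.
    residual_floor_mm : float
        Lower bound on the per-landmark residual scale used for
        z-scoring, preventing infinite z-scores on near-perfectly
        explained landmarks.
    clamp_sd : float
        Mode coefficients are clamped to ±clamp_sd·√eigenvalue during
        reconstruction, keeping reconstructions plausibly normal.

    Fitted attributes
    -----------------
    mean_shape_ : (n, 2) mean in the model frame (≈ mm of an
        average-sized training shape); modes_ : (k, 2n) orthonormal;
    eigenvalues_ : (k,) descending; residual_sd_ : (n,) per-landmark
        residual scale; facets_ : facet ranges transferred to fits.
    """

    def __init__(self, variance_target: float = 0.95,
                 residual_floor_mm: float = 0.05, clamp_sd: float = 3.0):
        self.variance_target = variance_target
        self.residual_floor_mm = residual_floor_mm
        self.clamp_sd = clamp_sd

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, facets: dict | None = None, bone: Bone | None = None):
        if not (0 < self.variance_target <= 1):
            raise ValueError("variance_target must be in (0, 1]")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (m, n, 2) landmark array")
        m, n, _ = X.shape
        if m < 3:
            raise ValueError("need at least 3 training shapes")
        aligned, transforms, mean = procrustes_align(X)

        # restore a metric frame: average centroid size in mm
        frame_scale = float(np.mean([centroid_size(x) for x in X]))
        aligned = aligned * frame_scale
        mean = mean * frame_scale

        # tangent-space projection: rescale each aligned shape onto the
        # hyperplane tangent to the consensus, removing the residual
        # scale coupling between Procrustes alignment and the PCA mean
        flat = aligned.reshape(m, 2 * n)
        c_flat = mean.ravel()
        gammas = (c_flat @ c_flat) / (flat @ c_flat)
        flat = flat * gammas[:, None]
        mean_flat = flat.mean(axis=0)
        centered = flat - mean_flat
        U, S, Vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = (S ** 2) / (m - 1)
        # numerically-zero modes sit ~ (eps * sigma_max)^2 below the top
        tol = max(eigvals.max(), 1.0) * 1e-18 if eigvals.size else 0.0
        nonzero = int(np.sum(eigvals > tol))
        k_max = int(min(2 * n - 4, m - 1, nonzero))
        if nonzero == 0 or k_max == 0:
            k = 0
        elif self.variance_target >= 1.0:
            k = k_max
        else:
            frac = np.cumsum(eigvals[:k_max]) / eigvals.sum()
            k = int(np.searchsorted(frac, self.variance_target - 1e-12) + 1)
            k = min(k, k_max)

        self.n_landmarks_ = n
        self.mean_shape_ = mean_flat.reshape(n, 2)
        # shapes were aligned to the GPA consensus, not to their average
        # (whose centroid size is slightly smaller); decompose() must use
        # the same target or training shapes leave the mode subspace
        self.alignment_target_ = mean  # already carries frame_scale
        self.modes_ = Vt[:k]
        self.eigenvalues_ = eigvals[:k]
        self.retained_variance_ = (float(eigvals[:k].sum() / eigvals.sum())
                                   if nonzero else 1.0)
        self.frame_scale_ = frame_scale

        coeffs = centered @ self.modes_.T if k else np.zeros((m, 0))
        recon = mean_flat + (coeffs @ self.modes_ if k else 0.0)
        res = (flat - recon).reshape(m, n, 2)
        rms = np.sqrt(np.mean(np.sum(res ** 2, axis=2), axis=0))
        self.residual_sd_ = np.maximum(rms, self.residual_floor_mm)
        self.facets_ = dict(facets) if facets else {}
        self.bone_ = Bone(bone) if bone is not None else None
        return self

    @property
    def n_modes_(self) -> int:
        return len(self.eigenvalues_)

    # -- projection ---------------------------------------------------------

    def _clamp(self, b: np.ndarray, clamp) -> np.ndarray:
        if clamp is None or self.n_modes_ == 0:
            return b
        lim = clamp * np.sqrt(self.eigenvalues_)
        return np.clip(b, -lim, lim)

    def decompose(self, shape: np.ndarray, clamp="default") -> ProjectionResult:
        """Align a shape into the model frame, project it onto the mode
        subspace (clamped), and map the reconstruction back."""
        if clamp == "default":
            clamp = self.clamp_sd
        shape = np.asarray(shape, dtype=float)
        tf = fit_similarity(shape, self.alignment_target_)
        c_flat = self.alignment_target_.ravel()
        raw = tf.apply(shape)
        gamma = float((c_flat @ c_flat) / (raw.ravel() @ c_flat))
        aligned = gamma * raw
        diff = (aligned - self.mean_shape_).ravel()
        b = self.modes_ @ diff if self.n_modes_ else np.zeros(0)
        b = self._clamp(b, clamp)
        recon_flat = self.mean_shape_.ravel() + (b @ self.modes_ if self.n_modes_ else 0.0)
        recon_model = recon_flat.reshape(-1, 2)
        recon = tf.inverse().apply(recon_model / gamma)
        return ProjectionResult(coefficients=b, aligned=aligned,
                                reconstruction_model=recon_model,
                                reconstruction=recon, transform=tf)

    def transform(self, X) -> np.ndarray:
        """Mode coefficients (unclamped) of each shape."""
        X = np.asarray(X, dtype=float)
        return np.stack([self.decompose(x, clamp=None).coefficients for x in X])

    def inverse_transform(self, B) -> np.ndarray:
        B = np.atleast_2d(np.asarray(B, dtype=float))
        flat = self.mean_shape_.ravel() + (B @ self.modes_ if self.n_modes_ else 0.0)
        return flat.reshape(len(B), self.n_landmarks_, 2)

    def reconstruct(self, X, clamp="default") -> np.ndarray:
        """Plausible-normal reconstruction of each shape, in its own frame."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.stack([self.decompose(x, clamp=clamp).reconstruction for x in X])
        return out[0] if single else out

    # -- persistence --------------------------------------------------------

    def save(self, path_prefix) -> None:
        """Write ``<prefix>.npz`` (arrays) + ``<prefix>.json`` (metadata)."""
        prefix = Path(path_prefix)
        np.savez(prefix.with_suffix(".npz"),
                 mean_shape=self.mean_shape_, modes=self.modes_,
                 eigenvalues=self.eigenvalues_, residual_sd=self.residual_sd_,
                 alignment_target=self.alignment_target_)
        meta = {
            "format_version": "1.0",
            "n_landmarks": self.n_landmarks_,
            "n_modes": self.n_modes_,
            "variance_target": self.variance_target,
            "retained_variance": self.retained_variance_,
            "residual_floor_mm": self.residual_floor_mm,
            "clamp_sd": self.clamp_sd,
            "frame_scale": self.frame_scale_,
            "bone": self.bone_.value if self.bone_ else None,
            "facets": {k: list(v) for k, v in self.facets_.items()},
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path_prefix) -> "PointDistributionModel":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        arrays = np.load(prefix.with_suffix(".npz"))
        model = cls(variance_target=meta["variance_target"],
                    residual_floor_mm=meta["residual_floor_mm"],
                    clamp_sd=meta.get("clamp_sd", 3.0))
        model.mean_shape_ = arrays["mean_shape"]
        model.alignment_target_ = arrays["alignment_target"]
        model.modes_ = arrays["modes"]
        model.eigenvalues_ = arrays["eigenvalues"]
        model.residual_sd_ = arrays["residual_sd"]
        model.n_landmarks_ = meta["n_landmarks"]
        model.retained_variance_ = meta["retained_variance"]
        model.frame_scale_ = meta["frame_scale"]
        model.bone_ = Bone(meta["bone"]) if meta.get("bone") else None
        model.facets_ = {k: tuple(v) for k, v in meta.get("facets", {}).items()}
        return model


def build_pdm(shapes, variance_target: float = 0.95,
              facets: dict | None = None, bone: Bone | None = None,
              residual_floor_mm: float = 0.05) -> PointDistributionModel:
    """Convenience wrapper: GPA + PCA in one call."""
    return PointDistributionModel(
        variance_target=variance_target,
        residual_floor_mm=residual_floor_mm,
    ).fit(np.asarray(shapes, dtype=float), facets=facets, bone=bone)


# ---------------------------------------------------------------------------
# fitting a model to a new contour


@dataclass
class ContourFit:
    shape: LandmarkedShape
    residual_mm: float
    converged: bool


def _closed_sampler(points: np.ndarray):
    """Return f(fracs) sampling a closed contour at arc-length fractions."""
    ext = np.vstack([points, points[:1]])
    s = cumulative_arclength(ext)
    total = s[-1]

    def sample(fracs: np.ndarray) -> np.ndarray:
        t = (np.asarray(fracs) % 1.0) * total
        return np.column_stack([np.interp(t, s, ext[:, 0]),
                                np.interp(t, s, ext[:, 1])])

    return sample


def fit_to_contour(model: PointDistributionModel, contour: Contour,
                   max_iter: int = 40, tol: float = 1e-4,
                   n_offsets: int | None = None) -> ContourFit:
    """Fit a bone PDM to an extracted contour and transfer facet labels.

    Correspondence is initialised by a cyclic start-index search: the
    model mean's per-landmark arc-length fractions are sampled from the
    contour at every cyclic offset and both traversal orientations, and
    the offset with the smallest Procrustes distance to the mean wins
    (ties → lowest offset).  The pose and clamped mode coefficients are
    then refined with closest-point (ICP-style) iterations against the
    densified contour, which resolves correspondence below the landmark
    spacing.  Returns the plausible-shape landmarks in image mm.
    """
    pts = contour.points
    n = model.n_landmarks_
    if n_offsets is None:
        n_offsets = n
    sample = _closed_sampler(pts)

    mean = model.mean_shape_
    mean_fracs = cumulative_arclength(np.vstack([mean, mean[:1]]))
    mean_fracs = (mean_fracs / mean_fracs[-1])[:-1]

    best = (np.inf, None)
    for orient in (1, -1):
        for j in range(n_offsets):
            fr = j / n_offsets + orient * mean_fracs
            cand = sample(fr)
            tf = fit_similarity(cand, mean)
            d = float(np.sum((tf.apply(cand) - mean) ** 2))
            if d < best[0] - 1e-12:
                best = (d, cand)
    targets = best[1]

    dense = np.vstack([pts, pts[:1]])
    recon = targets
    converged = False
    for _ in range(max_iter):
        proj = model.decompose(targets)
        move = float(np.max(np.hypot(*(proj.reconstruction - recon).T)))
        recon = proj.reconstruction
        targets = project_points_to_polyline(recon, dense)
        if move < tol:
            converged = True
            break

    # landmarks lie ON the observed boundary: the model supplies the
    # correspondence, the contour supplies the geometry.  The residual is
    # the gap between the plausible-shape reconstruction and the boundary.
    residual = float(np.mean(np.hypot(*(recon - targets).T)))
    shape = LandmarkedShape(bone=contour.bone, landmarks=targets,
                            facets=dict(model.facets_))
    return ContourFit(shape=shape, residual_mm=residual, converged=converged)
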