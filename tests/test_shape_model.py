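"""Procrustes/PDM correctness: alignment invariances, PCA identities,
contour fitting equivariance and facet transfer accuracy."""

import numpy as np
import pytest

from carpalkit.geometry import rotation_matrix
from carpalkit.mask_io import Bone, Contour, extract_contour, LABEL_TABLE
from carpalkit.shape_model import (
    DegenerateShapeError,
    LandmarkedShape,
    PointDistributionModel,
    build_pdm,
    facet_midpoint,
    fit_similarity,
    fit_to_contour,
    procrustes_align,
)
from carpalkit.synthetic import WristParams, generate_case


def unit_square(n_per_side=8):
    t = np.linspace(0, 1, n_per_side, endpoint=False)
    top = np.column_stack([t, np.zeros_like(t)])
    right = np.column_stack([np.ones_like(t), t])
    bottom = np.column_stack([1 - t, np.ones_like(t)])
    left = np.column_stack([np.zeros_like(t), 1 - t])
    return np.vstack([top, right, bottom, left])


def test_procrustes_identical_shapes():
    sq = unit_square()
    aligned, transforms, mean = procrustes_align([sq, sq])
    assert np.allclose(aligned[0], aligned[1], atol=1e-12)
    assert np.allclose(transforms[0].scale, transforms[1].scale)


def test_procrustes_similarity_invariance():
    sq = unit_square()
    other = 2.0 * sq @ rotation_matrix(90).T + np.array([5.0, -3.0])
    aligned, _, _ = procrustes_align([sq, other])
    rmsd = np.sqrt(np.mean(np.sum((aligned[0] - aligned[1]) ** 2, axis=1)))
    assert rmsd < 1e-9


def test_procrustes_mean_recovery_from_noise(rng):
    sq = unit_square()
    noisy = [sq + rng.normal(0, 0.01, sq.shape) for _ in range(3)]
    _, _, mean = procrustes_align(noisy)
    # compare in the mean's frame: align the true square to the mean
    tf = fit_similarity(sq, mean)
    assert np.max(np.abs(tf.apply(sq) - mean)) < 0.01 * 3


def test_procrustes_rejects_degenerate():
    with pytest.raises(DegenerateShapeError):
        procrustes_align([np.zeros((5, 2)), unit_square()[:5]])


def test_pdm_identical_training_shapes():
    sq = unit_square()
    model = build_pdm([sq, sq, sq])
    assert model.n_modes_ == 0
    recon = model.reconstruct(sq, clamp=None)
    assert np.max(np.abs(recon - sq)) < 1e-8


def test_pdm_single_mode_matches_covariance_oracle(rng):
    """Shapes varying along one direction: exactly one nonzero eigenvalue
    equal to the top eigenvalue of the sample covariance."""
    base = unit_square()
    rng2 = np.random.default_rng(8)
    direction = rng2.normal(0, 1, base.shape)
    # make the mode orthogonal to the similarity group at the base shape
    # (translations, scaling, rotation), so alignment cannot absorb or
    # distort it and the variation is purely one shape mode
    centred = base - base.mean(axis=0)
    basis = [np.tile([1.0, 0.0], (len(base), 1)),
             np.tile([0.0, 1.0], (len(base), 1)),
             centred, np.column_stack([-centred[:, 1], centred[:, 0]])]
    for b in basis:
        direction -= (direction.ravel() @ b.ravel()) / (b.ravel() @ b.ravel()) * b
    direction = direction / np.linalg.norm(direction)
    ts = np.array([-0.03, -0.01, 0.0, 0.01, 0.03])
    shapes = np.stack([base + t * direction for t in ts])
    model = PointDistributionModel(variance_target=1.0).fit(shapes)
    nonzero = model.eigenvalues_[
        model.eigenvalues_ > 1e-6 * model.eigenvalues_.max()]
    assert len(nonzero) == 1

    # independent oracle: eigendecomposition of the covariance of the
    # aligned, tangent-projected training shapes
    aligned, _, mean = procrustes_align(shapes)
    scale = np.mean([np.sqrt(np.sum((s - s.mean(0)) ** 2)) for s in shapes])
    flat = (aligned * scale).reshape(len(shapes), -1)
    c = (mean * scale).ravel()
    flat = flat * ((c @ c) / (flat @ c))[:, None]
    top = np.sort(np.linalg.eigvalsh(np.cov(flat.T)))[-1]
    assert nonzero[0] == pytest.approx(top, rel=1e-6)


def test_pdm_full_variance_reconstructs_training(rng):
    shapes = np.stack([unit_square() + rng.normal(0, 0.02, (32, 2))
                       for _ in range(6)])
    model = PointDistributionModel(variance_target=1.0).fit(shapes)
    recon = model.reconstruct(shapes, clamp=None)
    rmsd = np.sqrt(np.mean(np.sum((recon - shapes) ** 2, axis=2)))
    assert rmsd < 1e-8


def test_pdm_coefficient_variance_equals_eigenvalues(rng):
    shapes = np.stack([unit_square() + rng.normal(0, 0.05, (32, 2))
                       for _ in range(8)])
    model = PointDistributionModel(variance_target=1.0).fit(shapes)
    coeffs = model.transform(shapes)
    var = coeffs.var(axis=0, ddof=1)
    assert np.allclose(var, model.eigenvalues_, atol=1e-6)


def test_pdm_requires_enough_shapes():
    with pytest.raises(ValueError):
        build_pdm([unit_square(), unit_square()])


def test_pdm_save_load_roundtrip(tmp_path, rng):
    shapes = np.stack([unit_square() + rng.normal(0, 0.02, (32, 2))
                       for _ in range(5)])
    model = build_pdm(shapes, facets={"top": (0, 9)}, bone=Bone.LUNATE)
    model.save(tmp_path / "m")
    back = PointDistributionModel.load(tmp_path / "m")
    assert np.allclose(back.mean_shape_, model.mean_shape_)
    assert np.allclose(back.modes_, model.modes_)
    assert back.facets_ == {"top": (0, 9)}
    assert back.bone_ == Bone.LUNATE


# ---------------------------------------------------------------------------
# facet midpoints


def test_facet_midpoint_cases():
    shape = LandmarkedShape(
        bone=Bone.LUNATE,
        landmarks=np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0], [4.0, 4.0]]),
        facets={"two": (0, 2), "three": (0, 3)})
    assert np.allclose(facet_midpoint(shape, "two"), [1.0, 0.0])
    assert np.allclose(facet_midpoint(shape, "three"), [2.0, 0.0])
    with pytest.raises(KeyError):
        facet_midpoint(shape, "nope")


def test_facet_midpoint_quarter_circle():
    theta = np.linspace(0, np.pi / 2, 1001)
    pts = 10 * np.column_stack([np.cos(theta), np.sin(theta)])
    shape = LandmarkedShape(bone=Bone.LUNATE, landmarks=pts,
                            facets={"arc": (0, len(pts))})
    mid = facet_midpoint(shape, "arc")
    expected = 10 * np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
    assert np.linalg.norm(mid - expected) < 1e-4


# ---------------------------------------------------------------------------
# fitting to contours


@pytest.fixture(scope="module")
def lunate_model():
    from carpalkit.pipeline import train_models
    from carpalkit.synthetic import generate_cohort

    cohort = generate_cohort(15, seed=21, with_masks=False)
    stack = np.stack([c.contours_ap[Bone.LUNATE].points for c in cohort])
    facets = {k: tuple(v)
              for k, v in cohort[0].truth_facets["ap"]["lunate"].items()}
    return build_pdm(stack, facets=facets, bone=Bone.LUNATE), cohort


def test_fit_recovers_mean_shape(lunate_model):
    model, _ = lunate_model
    contour = Contour(bone=Bone.LUNATE, points=model.mean_shape_)
    fit = fit_to_contour(model, contour)
    assert fit.converged
    assert np.max(np.abs(np.sort(fit.shape.landmarks, axis=0)
                         - np.sort(model.mean_shape_, axis=0))) < 0.05
    proj = model.decompose(fit.shape.landmarks)
    assert np.all(np.abs(proj.coefficients) <
                  0.2 * np.sqrt(model.eigenvalues_) + 1e-6)


def test_fit_recovers_training_facets(lunate_model):
    """Facet midpoints of a fitted training contour within 0.5 mm of truth."""
    model, cohort = lunate_model
    case = cohort[3]
    truth = LandmarkedShape(
        bone=Bone.LUNATE, landmarks=case.contours_ap[Bone.LUNATE].points,
        facets={k: tuple(v)
                for k, v in case.truth_facets["ap"]["lunate"].items()})
    fit = fit_to_contour(model, case.contours_ap[Bone.LUNATE])
    for facet in ("lunate_scaphoid", "lunate_radius", "lunate_capitate"):
        d = np.linalg.norm(facet_midpoint(fit.shape, facet)
                           - facet_midpoint(truth, facet))
        assert d < 0.5, (facet, d)


def test_fit_similarity_equivariance(lunate_model):
    """Fitting a rotated+scaled contour yields the same landmarks up to
    that similarity transform."""
    model, cohort = lunate_model
    pts = cohort[5].contours_ap[Bone.LUNATE].points
    fit0 = fit_to_contour(model, Contour(bone=Bone.LUNATE, points=pts))
    R = rotation_matrix(30.0)
    moved = 1.5 * pts @ R.T + np.array([7.0, -2.0])
    fit1 = fit_to_contour(model, Contour(bone=Bone.LUNATE, points=moved))
    expected = 1.5 * fit0.shape.landmarks @ R.T + np.array([7.0, -2.0])
    assert np.max(np.hypot(*(fit1.shape.landmarks - expected).T)) < 0.1


def test_fit_from_extracted_mask_contour(lunate_model):
    model, _ = lunate_model
    case = generate_case(WristParams(seed=31), 0.2)
    ext = extract_contour(case.label_mask_ap == LABEL_TABLE[Bone.LUNATE],
                          0.2, Bone.LUNATE)
    fit = fit_to_contour(model, ext)
    assert fit.residual_mm < 0.1
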