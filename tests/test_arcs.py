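"""Carpal arc construction, plausible-normal reconstruction, z-scoring
and interruption detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carpalkit.arcs import (
    ARC_POINTS,
    ArcSet,
    build_arcs,
    detect_interruption,
    disruption_score,
    render_heatmap,
)
from carpalkit.geometry import rotation_matrix
from carpalkit.mask_io import Bone, View
from carpalkit.pipeline import case_study, fit_view, truth_shapes
from carpalkit.synthetic import WristParams, generate_case


@pytest.fixture(scope="module")
def normal_case():
    return generate_case(WristParams(seed=61), with_masks=False)


def measured_arcs(case, registry):
    shapes, _ = fit_view(case_study(case, View.NEUTRAL_AP_PA), registry, "ap")
    return build_arcs(shapes)


def max_turning_deg(arc):
    seg = np.diff(arc, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    cosang = np.clip(np.sum(seg[1:] * seg[:-1], axis=1), -1, 1)
    return float(np.degrees(np.arccos(cosang)).max())


def test_build_arcs_structure_and_smoothness(normal_case):
    arcset = build_arcs(truth_shapes(normal_case, "ap"))
    assert arcset.available == ["proximal", "middle", "distal"]
    for _, arc in arcset.items():
        assert arc.shape == (ARC_POINTS, 2)
        # radial -> ulnar ordering
        assert arc[-1, 0] > arc[0, 0]
        # smooth: generated arcs bend gently everywhere
        assert max_turning_deg(arc) < 25.0


def test_capitate_shift_is_local_to_distal_arc(normal_case):
    shapes = truth_shapes(normal_case, "ap")
    base = build_arcs(shapes)
    shifted = dict(shapes)
    cap = shapes[Bone.CAPITATE]
    shifted[Bone.CAPITATE] = type(cap)(bone=cap.bone,
                                       landmarks=cap.landmarks + [0.0, 3.0],
                                       facets=cap.facets)
    moved = build_arcs(shifted)
    assert np.allclose(moved.proximal, base.proximal)
    assert np.allclose(moved.middle, base.middle)
    assert np.max(np.abs(moved.distal - base.distal)) > 1.0


def test_missing_hamate_drops_distal_arc(normal_case):
    shapes = truth_shapes(normal_case, "ap")
    del shapes[Bone.HAMATE]
    arcset = build_arcs(shapes)
    assert arcset.distal is None
    assert arcset.proximal is not None and arcset.middle is not None


def test_arcs_require_neutral_view(normal_case):
    with pytest.raises(ValueError):
        build_arcs(truth_shapes(normal_case, "ap"), view=View.LATERAL)


# ---------------------------------------------------------------------------
# reconstruction and z-scores


def test_training_arcs_reconstruct_in_span(registry, train_cohort):
    """A normal training arc is (nearly) its own reconstruction."""
    det = registry.detector
    case = [c for c in train_cohort if not c.truth["interrupted"]][0]
    arcset = measured_arcs(case, registry)
    assessment = det.assess(arcset)
    for name in arcset.available:
        rmsd = np.sqrt(np.mean(np.sum(assessment.displacement[name] ** 2,
                                      axis=1)))
        assert rmsd < 0.25, name
    assert assessment.disruption_score < det.threshold


def test_model_mean_reconstructs_to_itself(registry):
    det = registry.detector
    arcs = {}
    for name, model in det.models_.items():
        posed = 1.3 * model.mean_shape_ @ rotation_matrix(12.0).T + [4.0, 2.0]
        arcs[name] = posed
    assessment = det.assess(ArcSet(**arcs))
    assert assessment.disruption_score == 0.0
    for name in det.models_:
        assert np.max(np.abs(assessment.displacement[name])) < 1e-6


def test_held_out_normals_calibrated(registry):
    """Mean z of held-out normal wrists is near 1 (well-calibrated
    residual scales)."""
    from carpalkit.synthetic import generate_cohort

    # held-out normals drawn from the same case mix as the training
    # cohort (incl. widened-but-aligned wrists and contour jitter)
    held_out = generate_cohort(8, seed=303, spacing_mm_per_px=0.2,
                               widened_frac=0.25)
    zs = []
    for case in held_out:
        assessment = registry.detector.assess(measured_arcs(case, registry))
        zs.append(np.concatenate(list(assessment.zscores.values())))
    mean_z = float(np.mean(np.concatenate(zs)))
    assert 0.5 <= mean_z <= 1.5, mean_z


def test_interrupted_case_scores_high(registry):
    case = generate_case(WristParams(subluxation_mm=3.0, seed=71), 0.2)
    assessment = registry.detector.assess(measured_arcs(case, registry))
    assert assessment.detected
    assert assessment.disruption_score >= registry.detector.threshold
    # the step-off concentrates on the distal arc, far above noise level
    assert np.max(assessment.zscores["distal"]) >= 5.0
    # and shows up as contiguous marker runs there
    assert assessment.markers["distal"]
    assert np.max(assessment.zscores["distal"]) > \
        np.max(assessment.zscores["proximal"])


def test_local_step_leaves_large_displacement():
    """Subspace-projection oracle on a toy arc model: a 3 mm step over a
    short arc segment cannot be absorbed by pose or the normal modes, so
    the displacement at the step stays large while the reconstruction
    stays smooth."""
    from carpalkit.shape_model import PointDistributionModel

    rng = np.random.default_rng(17)
    x = np.linspace(0, 60, 100)
    arcs = []
    for _ in range(20):
        amp = rng.uniform(8, 12)
        phase = rng.uniform(-0.2, 0.2)
        y = 40 - amp * np.sin(np.pi * (x / 60) + phase)
        arcs.append(np.column_stack([x, y]))
    model = PointDistributionModel(variance_target=0.95).fit(np.stack(arcs))

    observed = arcs[0].copy()
    observed[40:55, 1] += 3.0
    proj = model.decompose(observed)
    disp = np.hypot(*(observed - proj.reconstruction).T)
    assert disp[40:55].max() >= 1.5
    assert max_turning_deg(proj.reconstruction) < 20.0


def test_lengthened_only_case_not_detected(registry):
    """A widened SL gap without proximal subluxation lengthens the arcs
    but is not an interruption."""
    case = generate_case(WristParams(sl_gap_mm=4.2, seed=81), 0.2)
    assessment = registry.detector.assess(measured_arcs(case, registry))
    assert not assessment.detected


def test_score_invariant_to_similarity(registry):
    case = generate_case(WristParams(subluxation_mm=3.0, seed=91), 0.2)
    arcset = measured_arcs(case, registry)
    s0 = registry.detector.assess(arcset).disruption_score
    R = rotation_matrix(23.0)
    moved = ArcSet(**{name: 1.4 * arc @ R.T + [5.0, -3.0]
                      for name, arc in arcset.items()})
    s1 = registry.detector.assess(moved).disruption_score
    assert s0 == pytest.approx(s1, abs=0.01)


# ---------------------------------------------------------------------------
# disruption score semantics


def test_disruption_score_trivia():
    assert disruption_score([np.zeros(300)]) == 0.0
    z = np.zeros(300)
    z[:33] = 3.0
    assert disruption_score([z]) == pytest.approx(0.11)
    with pytest.raises(ValueError):
        disruption_score([z], z_crit=0.0)


@given(st.lists(st.floats(0, 5), min_size=10, max_size=50), st.integers(0, 9))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_disruption_score_monotone(zs, idx):
    z = np.asarray(zs)
    s0 = disruption_score([z])
    z2 = z.copy()
    z2[idx % len(z2)] += 1.0
    assert disruption_score([z2]) >= s0


def test_detect_interruption_threshold_rule(registry):
    case = generate_case(WristParams(seed=95), 0.2)
    assessment = registry.detector.assess(measured_arcs(case, registry))
    # re-evaluate the same assessment at explicit thresholds
    assessment.disruption_score = 0.10
    detected, _ = detect_interruption(assessment, threshold=0.11)
    assert not detected
    detected, _ = detect_interruption(assessment, threshold=0.10)
    assert detected


# ---------------------------------------------------------------------------
# rendering


def test_render_heatmap_preserves_size(registry):
    case = generate_case(WristParams(subluxation_mm=3.0, seed=97), 0.2)
    from carpalkit.pipeline import _label_image

    study = case_study(case, View.NEUTRAL_AP_PA)
    assessment = registry.detector.assess(measured_arcs(case, registry))
    bg = _label_image(study) * 30
    overlay = render_heatmap(assessment, bg, 0.2)
    assert overlay.shape == (*bg.shape, 3)
    assert overlay.dtype == np.uint8
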