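# carpalkit

Automated radiographic assessment of **carpal instability** from per-bone
wrist segmentations.

Carpal instability — the inability of the carpal bones to hold normal
alignment under load — is screened on conventional radiographs with three
measurements and one qualitative sign: the scapholunate (SL) joint
distance on the frontal (AP/PA) view, the SL and capitolunate (CL) angles
on the lateral view, and interruptions of Gilula's three carpal arcs.
These measurements are error-prone and unfamiliar outside musculoskeletal
radiology; `carpalkit` computes them reproducibly from per-bone label
masks (the output of any wrist segmentation model), for researchers and
engineers building or validating such measurement systems.

## What it computes

Given calibrated label masks (scaphoid, lunate, triquetrum, capitate,
hamate, third metacarpal base, distal radius) and a sidecar with the
pixel spacing, view and patient age:

* **SL joint distance** (AP/PA): the Euclidean distance between the
  mid-points of the facing scaphoid–lunate facets; abnormal if
  > 3.0 mm on neutral or > 3.7 mm on ulnar-deviated views.
* **SL angle** (lateral): the angle between the scaphoid long axis and
  the lunate mid-plane axis; normal in [30°, 60°].
* **CL angle** (lateral): capitate long axis vs. lunate axis; normal
  ≤ 30°.
* **Gilula's arcs + interruption detection** (neutral AP/PA): the three
  carpal arcs as 100-point polylines, their *hypothetical normal*
  reconstruction from a point distribution model (PDM) trained on
  non-interrupted wrists, per-point z-scores, and a **disruption
  score** — the fraction of arc points with z ≥ z₍crit₎ (2.0), flagged
  at an operating threshold of 0.11.

Articular facets are located by fitting per-bone PDMs (Procrustes
alignment + PCA over corresponded landmarks) to the extracted sub-pixel
contours; facet labels transfer from the model to the fitted landmarks.
Axes follow the facet mid-point construction: the capitate axis joins
its lunate- and metacarpal-facet mid-points, the lunate axis its radius-
and capitate-facet mid-points, and the scaphoid long axis is the
principal axis of its lateral contour.

A key behaviour of the arc detector: dissociations that only *lengthen*
the arcs (a widened SL gap with no proximal subluxation) are **not**
interruptions — the PDM training set includes widened-but-aligned
wrists, so pure lengthening stays inside the normal shape space and
scores low. Only true step-offs (bones subluxating proximally into a
widened joint space) are flagged.

Because clinical data cannot ship with the package, a parametric
**synthetic wrist generator** (`carpalkit.synthetic`) produces AP/PA and
lateral geometries with exact ground truth — controllable SL gap, SL/CL
angles, proximal capitate subluxation, patient scale/rotation and
contour jitter — used for training fixtures, testing and calibration.

The evaluation stack (`carpalkit.evalstats`) implements MAE,
Bland-Altman bias and limits of agreement, mean discrete Fréchet
distance between arc polylines, ROC/AUC with the Youden operating point,
stratified bootstrap CIs, paired permutation tests and the DeLong test.

## Worked example

```python
import numpy as np
from carpalkit import WristParams, generate_case, generate_cohort, train_models
from carpalkit.pipeline import measure_case

# train shape models on 30 synthetic normals (incl. widened-but-aligned)
train = generate_cohort(30, seed=11, widened_frac=0.25)
registry = train_models(train)

# a DISI-like wrist: widened SL gap AND a 3 mm proximal capitate shift
case = generate_case(WristParams(sl_gap_mm=4.0, sl_angle_deg=72.0,
                                 cl_angle_deg=24.0, subluxation_mm=3.0,
                                 seed=5), spacing_mm_per_px=0.2)
report = measure_case(case, registry)
print(f"SL distance : {report['sl_distance_mm']:.2f} mm "
      f"(abnormal: {report['sl_distance_abnormal']})")
print(f"SL angle    : {report['sl_angle_deg']:.1f} deg")
print(f"CL angle    : {report['cl_angle_deg']:.1f} deg")
print(f"disruption  : {report['disruption_score']:.2f} "
      f"(interrupted: {report['arc_interrupted']})")
```

prints

```
SL distance : 3.99 mm (abnormal: True)
SL angle    : 72.0 deg
CL angle    : 23.5 deg
disruption  : 0.29 (interrupted: True)
```

The measured SL distance (3.99 mm vs. the 4.0 mm ground truth, above the
3.0 mm neutral-view threshold) and SL angle (72° > 60°) are flagged
abnormal; 29% of arc points deviate significantly from the reconstructed
normal arcs, well above the 11% operating threshold, so the arcs are
reported interrupted. The CL angle (23.5°) stays below 30°.

## Command line

```sh
carpalkit synthesize --n 100 --interrupted-frac 0.5 --seed 7 --out cohort/
carpalkit train-models cohort/ --out models/
carpalkit measure cohort/case_0000 --models models/ --out out/
carpalkit evaluate out/ cohort/ --out eval.json
```

Exit codes: 0 ok, 2 input error, 3 model missing.

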