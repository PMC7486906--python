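# primatemocap

Markerless multiview 3D motion capture and behavior analysis for freely
moving primates.

Rhesus macaques move through large three-dimensional spaces on four limbs,
and their fur, flexible skin and curiosity make marker-based motion capture
impractical. The alternative is a dense ring of calibrated cameras around
the enclosure plus a 2D landmark detector per view: each body landmark is
detected independently in every image and triangulated into 3D. This
package implements everything around the neural detector — the multiview
geometry, the annotation-efficiency machinery that makes training such a
detector affordable, the physically plausible pose refinement, and the
behavioral analytics — together with a synthetic studio (camera rig,
articulated skeleton, noisy detection emulator) that stands in for the
detector and real recordings, so the whole pipeline runs and is tested
end to end on a laptop.

## What is implemented

**Camera geometry** (`camera_geometry`). Pinhole cameras with two-term
radial (Brown) distortion, calibration JSON IO, and three triangulators:
direct linear transform (DLT) least squares, RANSAC consensus (each camera
pair proposes a 3D point X; the candidate maximizing the number of views
with reprojection error ‖Π_i(X) − x_i‖ < 10 px wins and is refit by DLT
over its inliers), and mean-shift mode seeking over the pairwise candidate
cloud.

**Synthetic studio** (`synthetic_studio`). A 62-camera, two-level rig
around a 2.45 × 2.45 × 2.75 m enclosure; a 13-landmark skeleton (nose,
head, neck, shoulders, hands, hip, knees, feet, tail) executing scripted
actions — sit, stand, walk, climb, climb supine, jump — with limb lengths
conserved exactly; detection emulation with Gaussian pixel noise, gross
outliers, misses and torso-capsule self-occlusion; and detector-style
46 × 46 × 14 Gaussian response maps (13 landmarks + background).

**Annotation pipeline** (`annotation_pipeline`). Keyframe selection by
center-of-mass displacement; distance-adaptive crop windows (side ∝ 1/d,
resized to 368 × 368); greedy max-min informative-view proposal; geometric
verification of human annotations (entries with reprojection error above
10 px are flagged); cross-view propagation of verified landmarks into all
other views (3 annotated views label ~60, a ~20× amplification); and the
nine-member affine augmentation family (±30° rotations, ±20% shifts,
±10% scalings, horizontal flip with left/right label swap).

**Pose reconstruction** (`pose_reconstruction`). Response-map decoding,
per-frame per-landmark RANSAC triangulation, limb-length estimation
(per-edge median distance over time), and kinematic-chain refinement: for
each landmark X_t, minimize

```
Σ_i ‖Π_i(X_t) − x_{i,t}‖²  +  w_L (‖X_t − Y_t‖ − L_{X,Y})²  +  w_T ‖X_{t−1} − X_t‖²
```

by quasi-Newton (BFGS, gradient threshold 1e−5), where Y_t is the parent
landmark and L_{X,Y} the estimated limb length. The neck is refined first
(no limb term), then children breadth-first, sweeping frames forward.

**Behavior analysis** (`behavior_analysis`). Canonical pose features
(neck at origin, y-axis along gravity, z-axis along the spine, spine
length normalized to 1 → a 36-vector), the view-contaminated 26-vector 2D
baseline, UMAP embedding + density-based clustering, kNN action
classification, action transition matrices, two-animal tracking (k-means
separation with temporally stable identities), action co-occurrence and
body-centric proxemics polar histograms.

**Evaluation + CLI** (`evaluation`, `cli`). PCK@10 cm in 3D (per landmark
and overall), camera-count ablations against the full-rig reconstruction,
view-dependent accuracy binned by camera angle around the subject, and a
`primatemocap` command with `simulate / keyframes / reconstruct / refine /
behavior / evaluate / run` subcommands over a YAML config.

## Worked example

```python
import numpy as np
from primatemocap import (
    MotionScript, NoiseModel, make_rig, simulate_motion, emulate_detections,
    reconstruct_sequence, estimate_limb_lengths, refine_chain, pck3d)
from primatemocap.core import default_skeleton

skeleton = default_skeleton()
rig = make_rig()                                  # 62 calibrated cameras
script = MotionScript.from_pairs([("walk", 2.0), ("sit", 2.0)])
gt, labels = simulate_motion(skeleton, script, seed=3)

noise = NoiseModel(pixel_sigma=2.0, outlier_prob=0.10, occlusion=True, seed=5)
detections = emulate_detections(gt, rig, noise, skeleton)

raw = reconstruct_sequence(detections, rig,
                           landmark_names=list(skeleton.landmark_names))
lengths = estimate_limb_lengths(raw, skeleton)
refined = refine_chain(raw, detections, rig, skeleton, lengths)

print(f"PCK@10cm: {100 * pck3d(raw, gt)['overall']:.1f}%")
err = lambda p: np.linalg.norm(p.positions - gt.positions, axis=2)[p.valid].mean()
print(f"mean 3D error raw {1000 * err(raw):.2f} mm -> refined {1000 * err(refined):.2f} mm")
```

Output:

```
PCK@10cm: 100.0%
mean 3D error raw 2.47 mm -> refined 2.21 mm
```

With 2 px detector noise, 10% gross outliers and self-occlusion on, every
landmark instance lands within the 10 cm tolerance; the kinematic
refinement then shaves roughly 10% off the mean 3D error by enforcing
constant limb lengths and temporal smoothness.

The same pipeline from the shell:

```sh
primatemocap run --config examples/pipeline.yaml --out-dir out/
```

writes calibration, detections (COCO-keypoints JSON), raw/refined pose
CSVs, action labels, transition matrices, metrics and plots under `out/`.

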