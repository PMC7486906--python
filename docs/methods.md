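# Methods

This note documents the models, conventions, parameter choices and known
limitations of primatemocap, in the order the pipeline runs.

## Coordinate conventions

World frame: meters, z up, origin at the enclosure floor center. Pixels:
0-based, x right, y down, coordinates refer to pixel centers. The lens
model is a pinhole with two-term radial (Brown) distortion; the real
system uses fisheye lenses, but the pipeline mathematics is agnostic to
the projection model, so the simpler model is the default contract and the
synthetic rig is distortion-free. Undistortion is a 25-round fixed-point
iteration, exact to below 1e−9 px for |k1|, |k2| ≤ 0.3 within the radius
where the radial model is invertible (strong negative k2 makes extreme
corners non-invertible for any method; such pixels cannot arise from the
forward model in the first place).

## Triangulation

DLT stacks the homogeneous constraints from undistorted normalized
coordinates and takes the smallest-right-singular-vector solution. The
design matrix's condition number (excluding the solution direction) above
1e8 signals near-parallel rays and raises a degenerate-geometry error.

RANSAC enumerates all C(n, 2) camera pairs exhaustively for rigs up to 62
cameras — removing sampling variance and making results reproducible by
construction — and falls back to seeded random pairs beyond that.
Candidates come from the two-ray midpoint method; the consensus criterion
is reprojection error below the inlier threshold (default 10 px, the same
gate used for annotation verification). The winning candidate is refit by
DLT over its inliers; ties are broken by lower mean inlier error, then
enumeration order, so the procedure is fully deterministic. With zero
outliers every view is an inlier of the best candidate and the final
refit over all views is bit-identical to plain DLT.

Mean-shift triangulation builds the same pairwise candidate cloud and
climbs to the densest mode with a Gaussian kernel. The bandwidth default
(0.05 m) is a package choice sized to the rig's triangulation noise; in
the infinite-bandwidth limit the mode estimate degenerates to the cloud
mean, which the tests pin down.

## The synthetic studio

The rig places cameras on `n_levels` horizontal rings of radius
half-diagonal + 0.15 m, evenly spaced in azimuth starting at 45° (so
corner-facing cameras exist on a square enclosure), staggered by half a
spacing on alternate levels, all aimed at the enclosure center. Defaults:
62 cameras, 2 levels, 1280 × 1024 images, 450 px focal length — chosen so
a macaque-sized subject spans a few hundred pixels anywhere in the
2.45 × 2.45 × 2.75 m enclosure.

Motion is built from per-action body-frame templates (forward / right /
up offsets from the neck) with the skeleton assembled parent-to-child as
`child = parent + rest_length · unit(direction)`, so per-frame limb
lengths equal the rest lengths exactly, by construction. Action
primitives: sit (quasi-static, spine tilted ~24° from vertical), stand
(bipedal upright stance — macaques stand bipedally, and the upright torso
is what self-occludes the far hand), walk (quadrupedal, 0.42 m/s, 2 Hz
sinusoidal limb swing, heading random-walk with wall avoidance), climb
(glide to the nearest wall, then sinusoidal vertical traverse between
1.05 and 2.05 m), climb supine (inverted traverse under the ceiling,
limbs up), and jump (ballistic center-of-mass arcs with g = 9.81 m/s²).
Segments are joined by a 0.5 s neck-position ease (skipped entering a
jump so the arc stays exactly parabolic), and the neck height is clamped
per frame so every landmark stays inside the enclosure while easing
between action heights. Temporally smoothed direction jitter (σ = 15 mm,
EMA α = 0.2) keeps poses from being perfectly periodic.

Detections emulate an imperfect landmark detector: per (frame, camera,
landmark) a miss with probability `miss_prob`, else a uniform-random
in-image pixel with probability `outlier_prob`, else the exact projection
plus isotropic Gaussian noise. Self-occlusion intersects the viewing ray
with a torso capsule (neck–hip segment, radius 0.12 m — a plumbing choice
sized to macaque morphology); landmarks lying on the capsule (neck, hip,
head) are body surface and never self-hidden. Occluded landmarks default
to misses; setting `occluded_sigma` instead reports them with inflated
noise, emulating a detector that hallucinates occluded joints — the
view-dependent accuracy analysis uses this mode, the reconstruction and
ablation studies use miss semantics.

What the generator does **not** emulate: appearance (no images are
rendered, so nothing tests the detector itself), correlated detector
failures across cameras, multi-animal physical contact, and fisheye
distortion. Passing tests therefore validate the geometry, robustness and
analytics of the pipeline under a realistic error model — not the
performance of any particular neural detector on real footage.

## Response maps

The detector-facing representation is a 46 × 46 grid over a 368 × 368
crop (8 px per cell), 13 landmark channels plus one background channel
(1 − max over landmarks, clipped at 0). Rendering centers a Gaussian
(σ = 8 crop px by default) at the landmark's grid position; decoding takes
the argmax cell to its center pixel (8k + 4). Argmax ties — a landmark
exactly on a cell boundary renders symmetric neighbours — are broken
toward the higher index so the decoded cell is always the cell containing
the landmark; the render→decode round trip is exact to half a cell (4 px)
and bounded by one cell (8 px).

## Annotation efficiency

Keyframes are frames whose center of mass moved more than a threshold
(default 0.15 m) since the last retained keyframe. Measuring to the last
keyframe rather than the previous frame makes slow drift accumulate:
quiescent stretches collapse to a single keyframe while bouts of
locomotion are sampled densely. On sit-dominated scripts this yields a
100–400× reduction in frames to annotate.

Crop windows are centered on the projected center of mass with side
`scale_const / distance`; the default `scale_const = 780 px·m` makes a
1 m subject span ~150 px at the rig's 5.2 m diagonal extreme, and ~55% of
the resized 368 px crop at typical ranges.

Geometric verification triangulates each landmark from its human
annotations and flags entries with reprojection error above 10 px.
Outliers are identified by leave-one-out refitting — dropping the view
whose removal most restores consistency — because least-squares leverage
spreads a single bad annotation onto its neighbours, so the largest
residual alone does not identify the culprit. With only two views an
inconsistency below the detectable limit cannot be localized; such
landmarks are reported unverifiable.

Propagation triangulates the unflagged annotations once per landmark and
projects into every camera with positive depth and an in-image pixel.
Propagated labels are occlusion-agnostic on purpose: a landmark hidden
behind the body still receives its projected label, which is what teaches
a detector to predict occluded joints. Amplification is exactly
(#visible views) / (#annotated views), about 20× on the default rig.

## Kinematic-chain refinement

Each landmark trajectory minimizes reprojection consistency plus a
limb-length prior to its parent plus temporal smoothness (see README for
the objective). Design choices:

- **Weights.** The three terms are dimensionally heterogeneous (px² vs
  m²); the printed form is an unweighted sum, so both weights default to
  1 and are exposed (`weights=(w_L, w_T)`).
- **Order.** Root (neck) first without the limb term, then breadth-first
  down the tree, frames swept forward; X_{t−1} is the already-refined
  value, and the smoothness term is dropped at t = 0.
- **Inlier gating.** The reprojection term uses only detections within
  10 px of the initialization — gross outliers already rejected by RANSAC
  would otherwise re-bias the least-squares term.
- **Solver.** BFGS with analytic gradients, gradient threshold 1e−5,
  100 iterations max. If the solver fails to improve the objective the
  initialization is kept, so the objective is non-increasing per
  (landmark, frame) by construction.
- **Gaps.** An invalid landmark with a valid parent is re-initialized at
  parent + rest_length along the previous frame's limb direction (straight
  down when no history exists); with no parent information it stays
  invalid.

Refinement strictly reduces per-edge limb-length variance and mean 3D
error at 1, 2 and 4 px detector noise. Limb-length *medians* are anchored
to the raw estimate by the prior itself, so they improve toward rest only
when noise (outliers, occlusion) leaves room above the sub-millimeter
floor — at 1 px noise the raw medians are already within ~1 mm of truth
and the comparison is dominated by noise.

## Behavior analytics

Canonical features place the neck at the origin, map gravity (world −z)
to the canonical +y axis, align canonical z with the horizontal projection
of the neck→hip axis and divide by spine length: a 36-vector invariant to
location, heading and size, and equivariant under left/right mirroring.
When the spine is parallel to gravity the heading falls back to the
shoulder axis (x = horizontal(left − right shoulder), z = x × y). The 2D
baseline is the raw 26-vector of image coordinates — deliberately
view-contaminated, which is exactly why it underperforms.

Clustering uses UMAP (2D, 30 neighbours, fixed seed) and DBSCAN on the
embedding with a k-distance heuristic radius; the paper-style visual
inspection of clusters is replaced by this parametrized, seeded grouping.
kNN classification uses k = 15 (odd; majority vote, ties broken by the
nearest neighbour among tied classes) — the source protocol does not fix
k, and accuracy on the synthetic episodes is flat for k in 5–31.

Two-animal tracking k-means-splits (k = 2) the per-frame 3D cloud of
pairwise-triangulated instance centroids (mixed-animal candidate pairs
are rejected by a 5 cm ray-gap gate), matches centers to the previous
frame (swapping only when it lowers total distance), flags frames with
centers closer than 0.15 m as ambiguous, and reconstructs each animal
independently. Identity from appearance is out of scope; the
nearest-neighbour tracker is a stand-in that is exact whenever the
centers never co-locate within the ambiguity radius.

Proxemics expresses the conspecific's neck in the focal animal's
body-centric horizontal frame: 0° along the facing direction (horizontal
neck→nose vector; fallback: perpendicular of the shoulder axis), angles
positive to the left, distance the horizontal range. The histogram is
normalized to total mass 1; frames with invalid necks are skipped and
counted.

## Evaluation protocols

PCK@τ (default τ = 10 cm): an instance counts where the reference is
valid; a missing prediction is incorrect; landmarks with no comparable
instances are excluded from the overall mean. Camera ablations pick
deterministic azimuth-uniform subsets (sorted by azimuth, evenly strided
— the two staggered levels alternate naturally) and score against the
full-rig reconstruction by default, ground truth optionally. The
view-dependent analysis signs the camera angle negative on the animal's
left, positive on the right, 0 dead ahead.

## Problem sizes

The shipped tests and acceptance script use deliberately scaled runs:
120-frame benchmark sequences (walk + sit) for reconstruction and
refinement, 300 frames for limb-length recovery, ~5000-frame six-action
sequences for clustering, five independent train/test episode pairs
(~16 s each) for classification, and five seeds for the ablation sweeps.
These sizes were chosen so the complete suite exercises every claim in
minutes while leaving the statistics comfortably clear of their
thresholds; all of them scale linearly if larger runs are wanted.

## Known limitations

- No image rendering: detector behavior is modeled, not reproduced.
- The 13-landmark set is a modeling choice (shoulders + hands, no
  elbows); the skeleton is fully configurable and nothing in the pipeline
  depends on the default naming except the motion templates.
- The hard limb-length gate (rejecting raw points violating the estimate
  by more than 50%) is available but off by default; the soft prior alone
  handles the synthetic error model.
- Fisheye (equidistant) projection, rolling shutter and calibration
  estimation are out of scope; calibration is consumed, never estimated.
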