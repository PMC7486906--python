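"""Behavior analytics on 3D pose sequences.

Turns reconstructed landmark trajectories into semantics:

* :func:`canonicalize` — subject-centric pose representation: neck at the
  origin, y-axis along gravity, z-axis along the (horizontal projection of
  the) neck-to-hip spine axis, all coordinates divided by the spine length.
  This removes location, heading and body size, leaving a 36-vector
  (12 non-neck landmarks x 3) that depends only on posture;
* :func:`vectorize_2d` — the deliberately view-contaminated 26-vector 2D
  baseline (13 landmarks x 2, no normalization);
* :func:`embed_and_cluster` — UMAP to 2D plus density-based grouping;
* :func:`classify_actions` — k-nearest-neighbor action classification;
* :func:`transition_matrix` — row-stochastic action transition counts;
* :func:`track_two_animals` — k-means separation of two animals' detections
  with temporally stable identities;
* :func:`cooccurrence` and :func:`proxemics` — joint action statistics and
  the body-centric polar histogram of a conspecific's position.

Axis conventions: world gravity (-z) maps to the canonical +y axis; the
polar angle in :func:`proxemics` is 0 degrees dead ahead of the focal
animal and positive to its left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.neighbors import NearestNeighbors

from .camera_geometry import CameraModel, _CameraStack, _ransac_core
from .core import ACTIONS, ActionLabels, DetectionSet, PoseSequence3D, Skeleton

__all__ = [
    "canonicalize", "canonicalize_sequence", "vectorize_2d",
    "embed_and_cluster", "classify_actions", "transition_matrix",
    "track_two_animals", "TwoAnimalDiagnostics",
    "cooccurrence", "PolarHistogram", "proxemics", "facing_direction",
]

_UP = np.array([0.0, 0.0, 1.0])
_GRAVITY = np.array([0.0, 0.0, -1.0])


# ---------------------------------------------------------------------------
# Canonical features
# ---------------------------------------------------------------------------

def canonicalize(pose: np.ndarray, skeleton: Skeleton) -> np.ndarray:
    """Subject-centric 36-vector representation of one 13-landmark pose.

    The neck is the origin; the canonical y-axis is the gravity direction;
    the canonical z-axis is the neck-to-hip spine axis projected onto the
    horizontal plane (Gram-Schmidt against gravity); x = y cross z.  All
    coordinates are divided by the spine length, and the neck entry is
    dropped (it is identically zero).  Invariant to translation, rotation
    about gravity and uniform scaling by construction.

    Raises on a zero-length spine.  When the spine is parallel to gravity
    the heading is taken from the shoulder axis instead (documented
    tie-break): x = horizontal(left_shoulder - right_shoulder), z = x cross y.
    """
    pose = np.asarray(pose, dtype=float)
    if pose.shape != (skeleton.n_landmarks, 3):
        raise ValueError(f"pose must be ({skeleton.n_landmarks}, 3)")
    neck = pose[skeleton.index("neck")]
    hip = pose[skeleton.index("hip")]
    spine = hip - neck
    spine_len = float(np.linalg.norm(spine))
    if spine_len < 1e-9:
        raise ValueError("zero-length spine: neck and hip coincide")

    y = _GRAVITY
    s_h = spine - (spine @ y) * y          # horizontal component of the spine
    if np.linalg.norm(s_h) > 1e-8 * spine_len:
        z = s_h / np.linalg.norm(s_h)
        x = np.cross(y, z)
    else:
        sh = pose[skeleton.index("left_shoulder")] - pose[skeleton.index("right_shoulder")]
        sh_h = sh - (sh @ y) * y
        n = np.linalg.norm(sh_h)
        if n < 1e-9:
            raise ValueError("spine parallel to gravity and degenerate shoulder axis")
        x = sh_h / n
        z = np.cross(x, y)

    R = np.stack([x, y, z])                # world -> canonical
    rel = (pose - neck) @ R.T / spine_len
    keep = [j for j, n_ in enumerate(skeleton.landmark_names) if n_ != "neck"]
    return rel[keep].reshape(-1)


def canonicalize_sequence(poses: PoseSequence3D, skeleton: Skeleton) -> tuple[np.ndarray, np.ndarray]:
    """(T, 36) canonical features and a (T,) validity mask.

    Frames whose neck or hip is invalid (or degenerate) are masked out.
    """
    T = poses.n_frames
    feats = np.full((T, 3 * (skeleton.n_landmarks - 1)), np.nan)
    ok = np.zeros(T, dtype=bool)
    for t in range(T):
        if not poses.valid[t].all():
            continue
        try:
            feats[t] = canonicalize(poses.positions[t], skeleton)
            ok[t] = True
        except ValueError:
            continue
    return feats, ok


def vectorize_2d(pose2d: np.ndarray) -> np.ndarray:
    """Flatten a full 13x2 pixel pose to the 26-vector 2D representation.

    Deliberately no normalization: the 2D baseline keeps image location and
    viewpoint, which is exactly the contamination the canonical 3D
    representation removes.  Raises if any landmark is missing (NaN).
    """
    p = np.asarray(pose2d, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pose2d must be (n_landmarks, 2)")
    if not np.all(np.isfinite(p)):
        raise ValueError("missing landmark in 2D pose")
    return p.reshape(-1)


# ---------------------------------------------------------------------------
# Embedding, clustering, classification
# ---------------------------------------------------------------------------

def embed_and_cluster(
    features: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 30,
    min_dist: float = 0.1,
    min_samples: int = 20,
    eps: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """UMAP to 2D with a fixed seed, then DBSCAN grouping on the embedding.

    Returns (embedding (N, 2), labels (N,)) where labels >= 0 are clusters
    and -1 marks noise points — together a partition of the input.  The
    DBSCAN radius defaults to a k-distance heuristic (75th percentile of
    the ``min_samples``-th neighbor distance) so it adapts to the embedding
    scale.  Deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) < 50:
        raise ValueError("need at least 50 feature vectors")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.allclose(X, X[0]):
        # degenerate: identical inputs collapse to a single cluster
        return np.zeros((len(X), 2)), np.zeros(len(X), dtype=int)

    import umap  # heavy import kept local

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    emb = reducer.fit_transform(X)
    if eps is None:
        nn = NearestNeighbors(n_neighbors=min_samples).fit(emb)
        kdist = nn.kneighbors(emb)[0][:, -1]
        eps = float(np.percentile(kdist, 75)) * 1.5
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    return emb, labels


def classify_actions(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    test_features: np.ndarray,
    k: int = 15,
    fps: float = 30.0,
) -> ActionLabels:
    """k-nearest-neighbor action classification in feature space.

    Majority vote among the k nearest training vectors (Euclidean); ties
    are broken by the label of the single nearest neighbor among the tied
    classes.  ``k`` must be odd (vote symmetry).
    """
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    train_labels = np.asarray(train_labels, dtype=object)
    if len(train_features) == 0:
        raise ValueError("empty training set")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be odd and >= 1")
    k_eff = min(k, len(train_features))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(train_features)
    _, idx = nn.kneighbors(test_features)
    out = np.empty(len(test_features), dtype=object)
    for i, neigh in enumerate(idx):
        votes = train_labels[neigh]
        uniq, counts = np.unique(votes.astype(str), return_counts=True)
        winners = set(uniq[counts == counts.max()])
        if len(winners) == 1:
            out[i] = next(iter(winners))
        else:
            out[i] = next(v for v in votes if v in winners)  # nearest tied class
    return ActionLabels(out, fps=fps)


def transition_matrix(labels: ActionLabels | Sequence[str]) -> np.ndarray:
    """6x6 row-stochastic matrix of consecutive action transitions.

    Rows/columns follow the fixed :data:`~primatemocap.core.ACTIONS` order;
    rows with no outgoing transitions are left all zero.
    """
    arr = labels.labels if isinstance(labels, ActionLabels) else np.asarray(labels, dtype=object)
    if len(arr) < 2:
        raise ValueError("need at least 2 frames")
    index = {a: i for i, a in enumerate(ACTIONS)}
    counts = np.zeros((len(ACTIONS), len(ACTIONS)))
    for a, b in zip(arr[:-1], arr[1:]):
        counts[index[a], index[b]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, counts / sums, 0.0)
    return out


# ---------------------------------------------------------------------------
# Two-animal tracking
# ---------------------------------------------------------------------------

@dataclass
class TwoAnimalDiagnostics:
    ambiguous_frames: list[int] = field(default_factory=list)
    degenerate_frames: list[int] = field(default_factory=list)
    n_swaps: int = 0


def _pairwise_cloud(stack: _CameraStack, cam_idx: np.ndarray, pixels: np.ndarray,
                    max_gap_m: float = 0.05) -> np.ndarray:
    """3D candidates from all cross-camera pairs of instance centroids."""
    from .camera_geometry import _pairwise_candidates
    import itertools as it
    sub = stack.subset(cam_idx)
    dirs = sub.rays(pixels)
    pairs = [(i, j) for i, j in it.combinations(range(len(cam_idx)), 2)
             if cam_idx[i] != cam_idx[j]]
    if not pairs:
        return np.empty((0, 3))
    cand, gap = _pairwise_candidates(sub.centers, dirs, np.asarray(pairs))
    keep = np.isfinite(cand).all(axis=1) & (gap < max_gap_m)
    return cand[keep]


def track_two_animals(
    detections: pd.DataFrame,
    cameras: Sequence[CameraModel],
    landmark_names: Sequence[str],
    seed: int = 0,
    ambiguity_radius_m: float = 0.15,
    inlier_threshold_px: float = 10.0,
    fps: float = 30.0,
) -> tuple[PoseSequence3D, PoseSequence3D, TwoAnimalDiagnostics]:
    """Split two animals' detections and reconstruct each with stable identity.

    ``detections`` is a detection table with an extra ``instance`` column:
    per camera and frame, landmarks are grouped into (at most two) detected
    body instances whose numbering is arbitrary and inconsistent across
    cameras.  Per frame, all cross-camera pairs of instance centroids are
    triangulated into a 3D candidate cloud (skew-ray pairs — mixed-animal
    matches — are rejected by a ray-gap gate); k-means with k=2 on the
    cloud yields the two body centers.  Identity across frames is kept by
    nearest-neighbor matching of centers to the previous frame, swapping
    only when that lowers the total distance.  Frames whose centers are
    closer than ``ambiguity_radius_m`` are flagged ambiguous; frames where
    the split collapses onto one center are flagged degenerate.  Camera
    instances are assigned to the animal whose center reprojects closer,
    and each animal is then reconstructed landmark by landmark.
    """
    req = {"frame", "camera_id", "landmark", "x", "y", "instance"}
    if not req <= set(detections.columns):
        raise ValueError(f"detections must have columns {sorted(req)}")
    stack = _CameraStack(cameras)
    cam_index = {c.camera_id: i for i, c in enumerate(cameras)}
    frames = np.sort(detections["frame"].unique())
    T = int(frames.max()) + 1 if len(frames) else 0
    L = len(landmark_names)
    name_to_j = {n: j for j, n in enumerate(landmark_names)}

    pos = np.full((2, T, L, 3), np.nan)
    val = np.zeros((2, T, L), dtype=bool)
    diag = TwoAnimalDiagnostics()
    prev_centers: np.ndarray | None = None
    rng = np.random.default_rng(seed)

    for frame in frames:
        sub = detections[detections["frame"] == frame]
        # per (camera, instance) centroid pixels
        cents = sub.groupby(["camera_id", "instance"])[["x", "y"]].mean()
        cam_idx = np.array([cam_index[c] for c, _ in cents.index], dtype=int)
        pixels = cents.to_numpy(dtype=float)
        cloud = _pairwise_cloud(stack, cam_idx, pixels)
        if len(cloud) < 4:
            continue
        km = KMeans(n_clusters=2, n_init=3, random_state=int(rng.integers(2 ** 31)))
        km.fit(cloud)
        centers = km.cluster_centers_
        sizes = np.bincount(km.labels_, minlength=2)
        if sizes.min() < 0.2 * sizes.sum() or \
                np.linalg.norm(centers[0] - centers[1]) < ambiguity_radius_m:
            if sizes.min() < 0.2 * sizes.sum():
                diag.degenerate_frames.append(int(frame))
            else:
                diag.ambiguous_frames.append(int(frame))
            continue
        if prev_centers is not None:
            direct = np.linalg.norm(centers - prev_centers, axis=1).sum()
            swapped = np.linalg.norm(centers[::-1] - prev_centers, axis=1).sum()
            if swapped < direct:
                centers = centers[::-1]
                diag.n_swaps += 1
        prev_centers = centers

        # assign each camera instance to the nearer projected center
        proj_err = np.stack([
            np.sqrt(stack.subset(cam_idx).sq_reprojection_errors(pixels, c[None, :])[:, 0])
            for c in centers
        ])  # (2, n_instances)
        owner = np.argmin(proj_err, axis=0)
        inst_keys = list(cents.index)
        owner_map = {key: int(o) for key, o in zip(inst_keys, owner)}

        for a in (0, 1):
            keys = {k for k, o in owner_map.items() if o == a}
            sel = sub[[(c, i) in keys for c, i in zip(sub["camera_id"], sub["instance"])]]
            for lm, grp in sel.groupby("landmark"):
                j = name_to_j.get(lm)
                if j is None or len(grp) < 2:
                    continue
                idx = np.array([cam_index[c] for c in grp["camera_id"]], dtype=int)
                res = _ransac_core(stack.subset(idx), grp[["x", "y"]].to_numpy(dtype=float),
                                   inlier_threshold_px)
                if res.valid:
                    pos[a, int(frame), j] = res.point
                    val[a, int(frame), j] = True

    names = tuple(landmark_names)
    return (PoseSequence3D(pos[0], val[0], names, fps=fps, stage="raw"),
            PoseSequence3D(pos[1], val[1], names, fps=fps, stage="raw"),
            diag)


# ---------------------------------------------------------------------------
# Co-occurrence and proxemics
# ---------------------------------------------------------------------------

def cooccurrence(labels_a: ActionLabels | Sequence[str],
                 labels_b: ActionLabels | Sequence[str]) -> np.ndarray:
    """6x6 joint frame counts of (action of A, action of B).

    Raises on length mismatch.  Display scaling (log(1 + count)) is left to
    :func:`log_counts`.
    """
    a = labels_a.labels if isinstance(labels_a, ActionLabels) else np.asarray(labels_a, dtype=object)
    b = labels_b.labels if isinstance(labels_b, ActionLabels) else np.asarray(labels_b, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label streams differ in length: {len(a)} vs {len(b)}")
    index = {act: i for i, act in enumerate(ACTIONS)}
    counts = np.zeros((len(ACTIONS), len(ACTIONS)))
    for la, lb in zip(a, b):
        counts[index[la], index[lb]] += 1
    return counts


def log_counts(counts: np.ndarray) -> np.ndarray:
    """log(1 + count) display transform for co-occurrence matrices."""
    return np.log1p(counts)


def facing_direction(pose: np.ndarray, skeleton: Skeleton) -> np.ndarray:
    """Horizontal unit vector the animal faces, from the neck-to-nose axis.

    Falls back to the perpendicular of the shoulder axis (right-handed, so
    it still points forward) when the head points straight up or down.
    """
    neck = pose[skeleton.index("neck")]
    nose = pose[skeleton.index("nose")]
    f = nose - neck
    f[2] = 0.0
    n = np.linalg.norm(f)
    if n > 1e-8:
        return f / n
    sh = pose[skeleton.index("left_shoulder")] - pose[skeleton.index("right_shoulder")]
    f = np.cross(sh, _UP)
    f[2] = 0.0
    n = np.linalg.norm(f)
    if n < 1e-9:
        raise ValueError("facing direction undefined: degenerate head and shoulders")
    return f / n


@dataclass
class PolarHistogram:
    """Normalized polar histogram over (distance, bearing) bins."""

    r_edges: np.ndarray          # meters, len R+1
    theta_edges: np.ndarray      # degrees in [-180, 180], len TH+1
    mass: np.ndarray             # (R, TH), sums to 1 when any frame counted
    n_frames: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.mass < 0):
            raise ValueError("histogram mass must be nonnegative")


def proxemics(
    poses_a: PoseSequence3D,
    poses_b: PoseSequence3D,
    skeleton: Skeleton,
    r_edges: np.ndarray | None = None,
    theta_edges: np.ndarray | None = None,
) -> PolarHistogram:
    """Body-centric polar histogram of animal B's position around animal A.

    Per frame, B's neck is expressed in A's body-centric horizontal frame:
    origin at A's neck, 0 degrees along A's facing direction, angles
    positive to A's left.  Frames with invalid necks (or undefined facing)
    are skipped and counted.  The histogram is normalized to sum to 1.
    """
    if poses_a.n_frames != poses_b.n_frames:
        raise ValueError("pose sequences must be frame-aligned")
    if r_edges is None:
        r_edges = np.linspace(0.0, 3.0, 13)
    if theta_edges is None:
        theta_edges = np.linspace(-180.0, 180.0, 25)
    r_edges = np.asarray(r_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)

    neck_j = skeleton.index("neck")
    rs, ths = [], []
    skipped = 0
    for t in range(poses_a.n_frames):
        if not (poses_a.valid[t, neck_j] and poses_b.valid[t, neck_j]):
            skipped += 1
            continue
        try:
            f = facing_direction(poses_a.positions[t], skeleton)
        except ValueError:
            skipped += 1
            continue
        d = poses_b.positions[t, neck_j] - poses_a.positions[t, neck_j]
        d_h = np.array([d[0], d[1]])
        r = float(np.linalg.norm(d_h))
        cosv = f[0] * d_h[0] + f[1] * d_h[1]
        sinv = f[0] * d_h[1] - f[1] * d_h[0]     # positive when B is to A's left
        theta = float(np.degrees(np.arctan2(sinv, cosv)))
        rs.append(r)
        ths.append(theta)
    hist, _, _ = np.histogram2d(rs, ths, bins=[r_edges, theta_edges])
    total = hist.sum()
    mass = hist / total if total > 0 else hist
    return PolarHistogram(r_edges, theta_edges, mass,
                          n_frames=len(rs), n_skipped=skipped)
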