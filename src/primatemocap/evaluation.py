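"""Evaluation protocols: PCK, camera-count ablations, view-dependent accuracy.

The headline metric is PCK@tolerance in 3D: the fraction of (frame,
landmark) instances reconstructed within a tolerance (default 10 cm) of a
reference, reported per landmark and overall (mean over landmarks).  The
reference can be ground truth (synthetic data) or the full-rig
reconstruction (the paper-style "pseudo ground truth" for ablations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior_analysis import facing_direction
from .camera_geometry import CameraModel, project_points
from .core import DetectionSet, PoseSequence3D, Skeleton
from .pose_reconstruction import reconstruct_sequence

__all__ = [
    "AblationSpec", "pck3d", "select_camera_subset",
    "inference_ablation", "view_dependent_accuracy",
]


@dataclass(frozen=True)
class AblationSpec:
    """Camera-count sweep specification."""

    camera_counts: tuple[int, ...] = (2, 4, 8, 16, 32, 48)
    tolerance_m: float = 0.10
    inlier_threshold_px: float = 10.0

    def __post_init__(self) -> None:
        if not self.tolerance_m > 0:
            raise ValueError("tolerance must be positive")
        if any(n < 2 for n in self.camera_counts):
            raise ValueError("camera counts below 2 cannot triangulate; drop them")


def pck3d(
    pred: PoseSequence3D,
    ref: PoseSequence3D,
    tolerance_m: float = 0.10,
) -> dict:
    """Percentage of correctly reconstructed landmark instances.

    An instance (frame, landmark) counts when the reference is valid there;
    it is correct when the prediction is valid and within ``tolerance_m``.
    Landmarks with zero comparable instances are reported NaN and excluded
    from the overall mean.

    Returns {"per_landmark": {name: fraction}, "overall": fraction}.
    """
    if pred.positions.shape != ref.positions.shape:
        raise ValueError("pred and ref must be aligned (same frames and landmarks)")
    err = np.linalg.norm(pred.positions - ref.positions, axis=2)
    correct = pred.valid & ref.valid & (err <= tolerance_m)
    per = {}
    fractions = []
    for j, name in enumerate(ref.landmark_names):
        denom = int(ref.valid[:, j].sum())
        if denom == 0:
            per[name] = float("nan")
            continue
        frac = float(correct[:, j].sum() / denom)
        per[name] = frac
        fractions.append(frac)
    overall = float(np.mean(fractions)) if fractions else float("nan")
    return {"per_landmark": per, "overall": overall}


def select_camera_subset(cameras: Sequence[CameraModel], n: int) -> list[CameraModel]:
    """Deterministic uniform-over-placement subset of ``n`` cameras.

    Cameras are ordered by azimuth of their optical centers (the two rig
    levels are azimuth-staggered, so the ordering alternates levels) and
    picked at evenly spaced indices.
    """
    if n < 2:
        raise ValueError("need at least 2 cameras")
    if n >= len(cameras):
        return list(cameras)
    az = [float(np.arctan2(c.center[1], c.center[0])) for c in cameras]
    order = np.argsort(az, kind="stable")
    picks = np.floor(np.arange(n) * len(cameras) / n).astype(int)
    return [cameras[order[p]] for p in picks]


def inference_ablation(
    detections: DetectionSet,
    cameras: Sequence[CameraModel],
    spec: AblationSpec = AblationSpec(),
    reference: PoseSequence3D | None = None,
    landmark_names: Sequence[str] | None = None,
    fps: float = 30.0,
) -> pd.DataFrame:
    """PCK as a function of the number of cameras used at inference.

    For each n, detections are restricted to a deterministic uniformly
    placed subset of n cameras and reconstructed; accuracy is PCK against
    ``reference`` — by default the full-rig reconstruction, mirroring the
    relative-accuracy protocol (ground truth can be passed for synthetic
    data).  Counts below 2 are skipped: triangulation needs two views.

    Returns a tidy table (n, landmark, pck) with landmark "overall" rows.
    """
    names = list(landmark_names) if landmark_names is not None else detections.landmarks
    if reference is None:
        reference = reconstruct_sequence(
            detections, cameras, landmark_names=names,
            inlier_threshold_px=spec.inlier_threshold_px, fps=fps)
    rows = []
    counts = sorted(set(c for c in spec.camera_counts if 2 <= c) | set())
    for n in counts:
        if n > len(cameras):
            continue
        subset = select_camera_subset(cameras, n)
        det_n = detections.filter_cameras([c.camera_id for c in subset])
        rec = reconstruct_sequence(det_n, subset, landmark_names=names,
                                   inlier_threshold_px=spec.inlier_threshold_px, fps=fps)
        # align frame axis with the reference
        T = reference.n_frames
        pos = np.full((T, len(names), 3), np.nan)
        valid = np.zeros((T, len(names)), dtype=bool)
        upto = min(T, rec.n_frames)
        pos[:upto] = rec.positions[:upto]
        valid[:upto] = rec.valid[:upto]
        rec = PoseSequence3D(pos, valid, tuple(names), fps=fps, stage="raw")
        res = pck3d(rec, reference, spec.tolerance_m)
        for lm, frac in res["per_landmark"].items():
            rows.append({"n": n, "landmark": lm, "pck": frac})
        rows.append({"n": n, "landmark": "overall", "pck": res["overall"]})
    return pd.DataFrame(rows)


def view_dependent_accuracy(
    detections: DetectionSet,
    gt_poses: PoseSequence3D,
    cameras: Sequence[CameraModel],
    skeleton: Skeleton,
    bins_deg: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-landmark detection error binned by camera angle around the subject.

    For every detection, the error is the pixel distance to the ground-truth
    projection; the angle is the signed horizontal angle of the camera
    relative to the animal's facing direction — negative when the camera is
    on the animal's left, positive on its right, 0 dead ahead.  Frames
    whose facing direction is undefined are skipped.

    Returns a table (landmark, bin_center_deg, median_px, q25_px, q75_px, n).
    """
    if bins_deg is None:
        bins_deg = np.linspace(-180.0, 180.0, 13)
    bins_deg = np.asarray(bins_deg, dtype=float)
    names = list(gt_poses.landmark_names)
    neck_j = names.index("neck")
    cam_map = {c.camera_id: c for c in cameras}

    # per-frame facing direction
    facing = np.full((gt_poses.n_frames, 2), np.nan)
    for t in range(gt_poses.n_frames):
        if not gt_poses.valid[t].all():
            continue
        try:
            f = facing_direction(gt_poses.positions[t], skeleton)
            facing[t] = f[:2]
        except ValueError:
            continue

    records = []
    for cam_id, grp in detections.df.groupby("camera_id", sort=True):
        cam = cam_map.get(cam_id)
        if cam is None:
            continue
        frames = grp["frame"].to_numpy(dtype=int)
        lms = grp["landmark"].to_numpy(dtype=object)
        pix = grp[["x", "y"]].to_numpy(dtype=float)
        j_idx = np.array([names.index(l) for l in lms])
        gt3 = gt_poses.positions[frames, j_idx]
        gt2, depth = project_points(cam, gt3)
        err = np.linalg.norm(pix - gt2, axis=1)
        f = facing[frames]
        necks = gt_poses.positions[frames, neck_j, :2]
        v = cam.center[:2] - necks
        v = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
        cosv = f[:, 0] * v[:, 0] + f[:, 1] * v[:, 1]
        sinv = f[:, 0] * v[:, 1] - f[:, 1] * v[:, 0]   # >0: camera on the left
        angle = -np.degrees(np.arctan2(sinv, cosv))     # negative = left side
        ok = np.isfinite(angle) & (depth > 0) & np.isfinite(err)
        for lm, a, e in zip(lms[ok], angle[ok], err[ok]):
            records.append((lm, a, e))

    df = pd.DataFrame(records, columns=["landmark", "angle_deg", "error_px"])
    out = []
    centers = 0.5 * (bins_deg[:-1] + bins_deg[1:])
    for lm, grp in df.groupby("landmark", sort=True):
        which = np.digitize(grp["angle_deg"], bins_deg) - 1
        for b, c in enumerate(centers):
            sel = grp["error_px"].to_numpy()[which == b]
            if len(sel) == 0:
                continue
            out.append({"landmark": lm, "bin_center_deg": float(c),
                        "median_px": float(np.median(sel)),
                        "q25_px": float(np.percentile(sel, 25)),
                        "q75_px": float(np.percentile(sel, 75)),
                        "n": int(len(sel))})
    return pd.DataFrame(out)
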