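"""Annotation-efficiency machinery.

The manual-annotation budget is the bottleneck of any supervised pose
detector, so this module implements the levers that shrink it:

* keyframe selection — only frames with large center-of-mass travel since
  the last retained keyframe are worth annotating;
* crop-window computation — subject-centered crops whose size is inversely
  proportional to subject-camera distance, so the subject appears at a
  constant pixel scale after resizing to 368 x 368;
* informative-view proposal — a small set of views with maximal visibility
  and maximal pairwise optical-center distance (wide baselines);
* geometric verification — annotations are triangulated and reprojected;
  entries off by more than 10 px are flagged as outliers;
* cross-view propagation — verified landmarks are triangulated once and
  projected into every other view, multiplying each manual annotation by
  the number of cameras that see the landmark;
* the affine augmentation family — nine label-preserving transforms
  (rotations, shifts, scalings, horizontal flip with left/right swap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .camera_geometry import (
    BehindCameraError,
    CameraModel,
    GeometryError,
    InsufficientViewsError,
    TriangulationResult,
    project,
    project_points,
    triangulate_dlt,
    triangulate_ransac,
)
from .core import Skeleton

__all__ = [
    "AnnotationSet", "CropWindow",
    "center_of_mass_3d", "select_keyframes", "crop_window",
    "propose_annotation_views", "verify_annotations", "propagate_labels",
    "affine_augment",
]

_ANNOTATION_COLUMNS = ["frame", "camera_id", "landmark", "x", "y", "source", "flagged"]

#: Default crop scaling: pixels * meters.  A 1 m subject 5.2 m from the
#: camera (the rig's diagonal extreme) then spans ~150 px, matching the
#: optics the crop convention was designed around.
DEFAULT_SCALE_CONST = 780.0


class AnnotationSet:
    """Human and propagated 2D landmark annotations.

    DataFrame columns: ``frame, camera_id, landmark, x, y, source, flagged``
    with source in {"human", "propagated"}; flagged is only meaningful for
    human annotations (geometric-verification outliers).
    (frame, camera_id, landmark) combinations are unique.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=_ANNOTATION_COLUMNS)
        missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        if df.duplicated(["frame", "camera_id", "landmark"]).any():
            raise ValueError("duplicate (frame, camera_id, landmark) annotations")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "AnnotationSet":
        df = pd.DataFrame(list(records))
        if "source" not in df:
            df["source"] = "human"
        if "flagged" not in df:
            df["flagged"] = False
        return cls(df[_ANNOTATION_COLUMNS])

    def for_frame(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    def humans(self) -> pd.DataFrame:
        return self.df[self.df["source"] == "human"]

    # -- IO ----------------------------------------------------------------

    def to_coco(self, landmark_names: Sequence[str], image_size=(1280, 1024)) -> dict:
        from .core import DetectionSet
        df = self.df.copy()
        df["confidence"] = 1.0
        det = DetectionSet(df[["frame", "camera_id", "landmark", "x", "y", "confidence", "source"]])
        coco = det.to_coco(landmark_names, image_size)
        flags = {(r.frame, r.camera_id, r.landmark) for r in self.df.itertuples() if r.flagged}
        for ann, im in zip(coco["annotations"], coco["images"]):
            ann["flagged_keypoints"] = [
                n for n in landmark_names if (im["frame"], im["camera_id"], n) in flags
            ]
        return coco

    @classmethod
    def from_coco(cls, coco: dict) -> "AnnotationSet":
        from .core import DetectionSet
        det = DetectionSet.from_coco(coco)
        df = det.df.drop(columns=["confidence"])
        img_by_id = {im["id"]: im for im in coco["images"]}
        flags = set()
        for ann in coco["annotations"]:
            im = img_by_id[ann["image_id"]]
            for n in ann.get("flagged_keypoints", []):
                flags.add((im["frame"], im["camera_id"], n))
        df["flagged"] = [
            (r.frame, r.camera_id, r.landmark) in flags for r in df.itertuples()
        ]
        return cls(df[_ANNOTATION_COLUMNS])

    def save_coco(self, path, landmark_names: Sequence[str], image_size=(1280, 1024)) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_coco(landmark_names, image_size), fh)

    @classmethod
    def load_coco(cls, path) -> "AnnotationSet":
        with open(path) as fh:
            return cls.from_coco(json.load(fh))


@dataclass(frozen=True)
class CropWindow:
    """Square subject-centered crop resized to ``output_size`` pixels."""

    camera_id: str
    center_px: tuple[float, float]
    side_px: float
    output_size: int = 368
    frame: int | None = None

    def __post_init__(self) -> None:
        if not self.side_px > 0:
            raise ValueError("side_px must be positive")

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center_px) - self.side_px / 2.0

    def image_to_crop(self, pixels: np.ndarray) -> np.ndarray:
        """Full-image pixels -> resized-crop pixels."""
        p = np.asarray(pixels, dtype=float)
        return (p - self.origin) * (self.output_size / self.side_px)

    def crop_to_image(self, pixels: np.ndarray) -> np.ndarray:
        p = np.asarray(pixels, dtype=float)
        return self.origin + p * (self.side_px / self.output_size)


# ---------------------------------------------------------------------------
# Center of mass and keyframes
# ---------------------------------------------------------------------------

def center_of_mass_3d(
    centroids: Mapping[str, tuple[float, float]],
    cameras: Mapping[str, CameraModel] | Sequence[CameraModel],
    inlier_threshold_px: float = 10.0,
) -> TriangulationResult:
    """Robustly triangulate per-view body centroids into a 3D center of mass.

    Raises :class:`InsufficientViewsError` with fewer than two views; gross
    outlier centroids (noisy segmentation) are rejected by RANSAC.
    """
    cam_map = {c.camera_id: c for c in cameras} if not isinstance(cameras, Mapping) else cameras
    obs = [(cam_map[cid], np.asarray(pix, dtype=float))
           for cid, pix in centroids.items() if cid in cam_map]
    if len(obs) < 2:
        raise InsufficientViewsError(f"center-of-mass needs >= 2 views, got {len(obs)}")
    return triangulate_ransac(obs, inlier_threshold_px=inlier_threshold_px)


def select_keyframes(
    com_trajectory: np.ndarray, displacement_threshold_m: float = 0.15
) -> list[int]:
    """Frames whose center of mass moved beyond the threshold.

    Displacement is measured to the last *retained* keyframe (cumulative,
    so slow drift still accumulates into new keyframes).  The first frame
    is always retained; with threshold 0 every frame is a keyframe.  Frames
    with non-finite centers are skipped.
    """
    com = np.asarray(com_trajectory, dtype=float)
    if com.ndim != 2 or len(com) < 1:
        raise ValueError("com_trajectory must be (T, 3) with T >= 1")
    keyframes: list[int] = []
    last: np.ndarray | None = None
    for i, c in enumerate(com):
        if not np.all(np.isfinite(c)):
            continue
        if last is None:
            keyframes.append(i)
            last = c
        elif np.linalg.norm(c - last) > displacement_threshold_m or \
                displacement_threshold_m == 0.0:
            keyframes.append(i)
            last = c
    return keyframes


# ---------------------------------------------------------------------------
# Crops and view proposal
# ---------------------------------------------------------------------------

def crop_window(
    com3: np.ndarray,
    camera: CameraModel,
    scale_const: float = DEFAULT_SCALE_CONST,
    output_size: int = 368,
    frame: int | None = None,
) -> CropWindow:
    """Subject-centered crop, side inversely proportional to distance.

    ``side_px = scale_const / distance(com3, camera center)`` so the
    subject spans a constant fraction of the resized crop regardless of
    range.  The window is clipped to the image bounds (its center shifts
    inward if necessary).
    """
    com3 = np.asarray(com3, dtype=float).reshape(3)
    center = project(camera, com3)    # raises BehindCameraError when invalid
    dist = float(np.linalg.norm(com3 - camera.center))
    side = scale_const / dist
    w, h = camera.image_size
    side = min(side, w, h)
    cx = float(np.clip(center[0], side / 2.0, w - side / 2.0))
    cy = float(np.clip(center[1], side / 2.0, h - side / 2.0))
    return CropWindow(camera_id=camera.camera_id, center_px=(cx, cy),
                      side_px=side, output_size=output_size, frame=frame)


def propose_annotation_views(
    com3: np.ndarray,
    cameras: Sequence[CameraModel],
    visibility: Mapping[str, float] | None = None,
    k: int = 3,
) -> list[str]:
    """Pick ``k`` informative views: maximal visibility, minimal redundancy.

    Greedy max-min selection: start from the most visible camera (highest
    visibility score; ties broken by camera order), then repeatedly add the
    candidate whose minimum distance to the already-selected optical
    centers is largest.  When fewer than ``k`` cameras see the subject,
    all visible ones are returned.
    """
    com3 = np.asarray(com3, dtype=float).reshape(3)
    candidates = []
    for cam in cameras:
        pix, depth = project_points(cam, com3)
        if depth > 0 and cam.contains(pix):
            score = 1.0 if visibility is None else float(visibility.get(cam.camera_id, 0.0))
            candidates.append((cam, score))
    if len(candidates) <= k:
        return [c.camera_id for c, _ in candidates]
    centers = np.asarray([c.center for c, _ in candidates])
    scores = np.asarray([s for _, s in candidates])
    selected = [int(np.argmax(scores))]
    while len(selected) < k:
        remaining = [i for i in range(len(candidates)) if i not in selected]
        dmin = [min(np.linalg.norm(centers[i] - centers[j]) for j in selected)
                for i in remaining]
        selected.append(remaining[int(np.argmax(dmin))])
    return [candidates[i][0].camera_id for i in selected]


# ---------------------------------------------------------------------------
# Geometric verification and propagation
# ---------------------------------------------------------------------------

def verify_annotations(
    annotations: AnnotationSet,
    cameras: Sequence[CameraModel],
    reproj_threshold_px: float = 10.0,
    frame: int | None = None,
) -> pd.DataFrame:
    """Check multiview consistency of human annotations for one frame.

    Each landmark is triangulated from its human annotations and
    reprojected into every annotated view.  While the worst reprojection
    error exceeds the threshold and more than two views remain, the view
    whose removal best restores consistency (smallest worst residual of a
    leave-one-out refit) is flagged and dropped — least-squares leverage
    spreads a single bad annotation onto its neighbours, so the worst
    residual alone does not identify the culprit.  Landmarks annotated in
    fewer than two views are reported unverifiable.

    Returns a table (frame, camera_id, landmark, error_px, flagged,
    unverifiable).
    """
    cam_map = {c.camera_id: c for c in cameras}
    df = annotations.humans()
    if frame is not None:
        df = df[df["frame"] == frame]
    out_rows = []
    for (frm, landmark), grp in df.groupby(["frame", "landmark"], sort=True):
        cams = [cam_map[cid] for cid in grp["camera_id"]]
        pix = grp[["x", "y"]].to_numpy(dtype=float)
        ids = list(grp["camera_id"])
        if len(cams) < 2:
            for cid in ids:
                out_rows.append(dict(frame=frm, camera_id=cid, landmark=landmark,
                                     error_px=np.nan, flagged=False, unverifiable=True))
            continue
        def fit_errors(subset):
            """Triangulate over subset; return per-view errors or None."""
            try:
                point = triangulate_dlt([(cams[i], pix[i]) for i in subset])
            except GeometryError:
                return None
            errs = np.empty(len(cams))
            for i in range(len(cams)):
                p, depth = project_points(cams[i], point)
                errs[i] = float(np.linalg.norm(p - pix[i])) if depth > 0 else np.inf
            return errs

        active = list(range(len(cams)))
        flagged: set[int] = set()
        errs = fit_errors(active)
        while errs is not None and len(active) > 2 and \
                max(errs[i] for i in active) > reproj_threshold_px:
            # leave-one-out: drop the view whose removal restores consistency
            best_i, best_errs, best_score = None, None, np.inf
            for i in active:
                rest = [j for j in active if j != i]
                e = fit_errors(rest)
                score = max(e[j] for j in rest) if e is not None else np.inf
                if score < best_score:
                    best_i, best_errs, best_score = i, e, score
            if best_i is None:
                flagged.update(active)
                errs = None
                break
            flagged.add(best_i)
            active.remove(best_i)
            errs = best_errs
        if errs is None:
            errors = np.full(len(cams), np.nan)
            flagged.update(active)
        else:
            errors = np.where(np.isfinite(errs), errs, np.nan)
            # a removed view may be reconciled by the final fit; a kept pair
            # can still be inconsistent only below the detectable limit
            flagged = {i for i in flagged if errs[i] > reproj_threshold_px}
        for i, cid in enumerate(ids):
            out_rows.append(dict(frame=frm, camera_id=cid, landmark=landmark,
                                 error_px=errors[i], flagged=i in flagged,
                                 unverifiable=False))
    return pd.DataFrame(out_rows,
                        columns=["frame", "camera_id", "landmark", "error_px",
                                 "flagged", "unverifiable"])


def save_flag_report(report: pd.DataFrame, path) -> None:
    """Write the verification report as a TSV of flagged entries."""
    flagged = report[report["flagged"]]
    flagged.to_csv(path, sep="\t", index=False,
                   columns=["frame", "camera_id", "landmark", "error_px"])


def propagate_labels(
    annotations: AnnotationSet,
    cameras: Sequence[CameraModel],
    reproj_threshold_px: float = 10.0,
) -> AnnotationSet:
    """Propagate verified annotations into every other view.

    Per landmark and frame: triangulate the unflagged human annotations,
    then project the 3D point into every camera where it is visible
    (positive depth, inside the image) and not already human-annotated.
    Propagated labels are occlusion-agnostic: a landmark hidden behind the
    body still receives its projected label, which is exactly what makes
    the downstream detector robust to occlusion.  Landmarks verified in
    fewer than two views are skipped.
    """
    report = verify_annotations(annotations, cameras, reproj_threshold_px)
    flags = {(r.frame, r.camera_id, r.landmark) for r in report.itertuples() if r.flagged}
    cam_map = {c.camera_id: c for c in cameras}

    base = annotations.df.copy()
    base["flagged"] = [
        (r.frame, r.camera_id, r.landmark) in flags if r.source == "human" else False
        for r in base.itertuples()
    ]
    new_rows = []
    humans = base[base["source"] == "human"]
    for (frm, landmark), grp in humans.groupby(["frame", "landmark"], sort=True):
        good = grp[~grp["flagged"]]
        if len(good) < 2:
            continue
        obs = [(cam_map[r.camera_id], np.array([r.x, r.y])) for r in good.itertuples()]
        try:
            point = triangulate_dlt(obs)
        except GeometryError:
            continue
        annotated = set(grp["camera_id"])
        for cam in cameras:
            if cam.camera_id in annotated:
                continue
            pix, depth = project_points(cam, point)
            if depth > 0 and cam.contains(pix):
                new_rows.append(dict(frame=frm, camera_id=cam.camera_id,
                                     landmark=landmark, x=float(pix[0]), y=float(pix[1]),
                                     source="propagated", flagged=False))
    combined = pd.concat([base, pd.DataFrame(new_rows, columns=_ANNOTATION_COLUMNS)],
                         ignore_index=True)
    return AnnotationSet(combined)


# ---------------------------------------------------------------------------
# Affine augmentation
# ---------------------------------------------------------------------------

def _affine(mat: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ mat[:, :2].T + mat[:, 2]


def affine_augment(
    labels: Mapping[str, tuple[float, float]],
    crop_size: int = 368,
    bilateral_pairs: Sequence[tuple[str, str]] = (),
    skeleton: Skeleton | None = None,
) -> list[dict]:
    """The family of nine affine label transforms for one cropped instance.

    Exactly nine: rotations of +-30 degrees about the crop center, shifts
    of 20% of the side left/right/up/down, scalings x1.1 and x0.9 about the
    center, and a horizontal flip.  The flip also swaps bilateral (left,
    right) landmark names.  Labels transformed outside the crop are set to
    ``None`` (invalid).

    Returns a list of dicts with keys ``name``, ``matrix`` (2x3) and
    ``labels``.
    """
    if skeleton is not None and not bilateral_pairs:
        bilateral_pairs = skeleton.bilateral_pairs
    c = (crop_size - 1) / 2.0
    shift = 0.2 * crop_size

    def rot(deg):
        a = np.radians(deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        t = np.array([c, c]) - R @ np.array([c, c])
        return np.hstack([R, t[:, None]])

    def shf(dx, dy):
        return np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]])

    def scl(s):
        return np.array([[s, 0.0, c * (1 - s)], [0.0, s, c * (1 - s)]])

    flip = np.array([[-1.0, 0.0, crop_size - 1.0], [0.0, 1.0, 0.0]])
    family = [
        ("rot+30", rot(30)), ("rot-30", rot(-30)),
        ("shift_left", shf(-shift, 0)), ("shift_right", shf(shift, 0)),
        ("shift_up", shf(0, -shift)), ("shift_down", shf(0, shift)),
        ("scale1.1", scl(1.1)), ("scale0.9", scl(0.9)),
        ("flip", flip),
    ]
    swap = {a: b for a, b in bilateral_pairs} | {b: a for a, b in bilateral_pairs}
    out = []
    for name, mat in family:
        new_labels: dict[str, tuple[float, float] | None] = {}
        for lm, pt in labels.items():
            target = swap.get(lm, lm) if name == "flip" else lm
            if pt is None:
                new_labels[target] = None
                continue
            q = _affine(mat, np.asarray(pt, dtype=float))
            inside = (0 <= q[0] <= crop_size - 1) and (0 <= q[1] <= crop_size - 1)
            new_labels[target] = (float(q[0]), float(q[1])) if inside else None
        out.append({"name": name, "matrix": mat, "labels": new_labels})
    return out
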