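"""Shared containers for the motion-capture pipeline.

These are the in-memory objects every stage exchanges: the articulated
skeleton (13 named landmarks in a kinematic tree rooted at the neck),
per-view 2D detections, 3D pose sequences, per-frame action labels and
per-edge limb lengths.  File formats (COCO-keypoints JSON for detections
and annotations, plain CSV for poses and labels) round-trip through the
helpers here.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed action vocabulary used by the motion scripts and the classifiers.
ACTIONS: tuple[str, ...] = ("sit", "stand", "walk", "climb", "climb_supine", "jump")


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Skeleton:
    """Kinematic tree over named landmarks.

    ``parent_of`` maps every landmark to its parent; exactly one landmark
    (the root, by default the neck) maps to ``None``.  ``rest_limb_lengths``
    gives the anatomical length of every (parent, child) edge in meters.
    ``bilateral_pairs`` lists (left, right) name pairs that swap under a
    mirror transform.
    """

    landmark_names: tuple[str, ...]
    parent_of: Mapping[str, str | None]
    rest_limb_lengths: Mapping[tuple[str, str], float]
    bilateral_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = set(self.landmark_names)
        if len(names) != len(self.landmark_names):
            raise ValueError("duplicate landmark names")
        roots = [n for n in self.landmark_names if self.parent_of.get(n) is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, got {roots}")
        # tree check: every node reaches the root without cycles
        for name in self.landmark_names:
            seen = set()
            node: str | None = name
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in parent map at {node!r}")
                seen.add(node)
                node = self.parent_of.get(node)
        for edge in self.edges:
            length = self.rest_limb_lengths.get(edge)
            if length is None or not length > 0:
                raise ValueError(f"edge {edge} needs a positive rest length")
        flat = [n for pair in self.bilateral_pairs for n in pair]
        if len(flat) != len(set(flat)):
            raise ValueError("bilateral pairs must be disjoint")

    @property
    def root(self) -> str:
        return next(n for n in self.landmark_names if self.parent_of.get(n) is None)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """(parent, child) pairs for every non-root landmark."""
        return tuple(
            (self.parent_of[n], n) for n in self.landmark_names if self.parent_of.get(n) is not None
        )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    def index(self, name: str) -> int:
        return self.landmark_names.index(name)

    def children_of(self, name: str) -> list[str]:
        return [n for n in self.landmark_names if self.parent_of.get(n) == name]

    def bfs_order(self) -> list[str]:
        """Landmarks root-first, breadth-first down the tree."""
        order, queue = [], deque([self.root])
        while queue:
            node = queue.popleft()
            order.append(node)
            queue.extend(self.children_of(node))
        return order

    def mirror_name(self, name: str) -> str:
        for left, right in self.bilateral_pairs:
            if name == left:
                return right
            if name == right:
                return left
        return name


#: Default 13-landmark macaque skeleton.  The exact landmark set is
#: configurable; this default uses shoulders + hands (no elbows) with five
#: midline points (nose, head, neck, hip, tail).
DEFAULT_LANDMARKS: tuple[str, ...] = (
    "nose", "head", "neck",
    "left_shoulder", "right_shoulder",
    "left_hand", "right_hand",
    "hip",
    "left_knee", "right_knee",
    "left_foot", "right_foot",
    "tail",
)

_DEFAULT_PARENTS: dict[str, str | None] = {
    "neck": None,
    "head": "neck",
    "nose": "head",
    "left_shoulder": "neck",
    "right_shoulder": "neck",
    "left_hand": "left_shoulder",
    "right_hand": "right_shoulder",
    "hip": "neck",
    "left_knee": "hip",
    "right_knee": "hip",
    "left_foot": "left_knee",
    "right_foot": "right_knee",
    "tail": "hip",
}

# Rest limb lengths in meters, sized to an adult rhesus macaque.
_DEFAULT_LENGTHS: dict[tuple[str, str], float] = {
    ("neck", "head"): 0.09,
    ("head", "nose"): 0.08,
    ("neck", "left_shoulder"): 0.10,
    ("neck", "right_shoulder"): 0.10,
    ("left_shoulder", "left_hand"): 0.28,
    ("right_shoulder", "right_hand"): 0.28,
    ("neck", "hip"): 0.32,
    ("hip", "left_knee"): 0.16,
    ("hip", "right_knee"): 0.16,
    ("left_knee", "left_foot"): 0.18,
    ("right_knee", "right_foot"): 0.18,
    ("hip", "tail"): 0.25,
}

_DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("left_shoulder", "right_shoulder"),
    ("left_hand", "right_hand"),
    ("left_knee", "right_knee"),
    ("left_foot", "right_foot"),
)


def default_skeleton() -> Skeleton:
    """The default 13-landmark macaque skeleton rooted at the neck."""
    return Skeleton(
        landmark_names=DEFAULT_LANDMARKS,
        parent_of=dict(_DEFAULT_PARENTS),
        rest_limb_lengths=dict(_DEFAULT_LENGTHS),
        bilateral_pairs=_DEFAULT_PAIRS,
    )


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

_DETECTION_COLUMNS = ["frame", "camera_id", "landmark", "x", "y", "confidence", "source"]


class DetectionSet:
    """Per (frame, camera, landmark) 2D pixel observations.

    Thin wrapper over a pandas DataFrame with columns
    ``frame, camera_id, landmark, x, y, confidence, source`` where source is
    one of ``{"human", "propagated", "detector"}``.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=_DETECTION_COLUMNS)
        missing = [c for c in _DETECTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"detection table missing columns {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame"].unique())

    @property
    def landmarks(self) -> list[str]:
        return sorted(self.df["landmark"].unique())

    def for_frame(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    def filter_cameras(self, camera_ids: Iterable[str]) -> "DetectionSet":
        keep = set(camera_ids)
        return DetectionSet(self.df[self.df["camera_id"].isin(keep)].copy())

    # -- COCO-keypoints-style JSON -------------------------------------------------

    def to_coco(self, landmark_names: Sequence[str], image_size: tuple[int, int] = (1280, 1024)) -> dict:
        """Serialize to a COCO-keypoints-style dict (one image per frame/camera)."""
        names = list(landmark_names)
        images, annotations = [], []
        image_ids: dict[tuple[int, str], int] = {}
        for (frame, cam), grp in self.df.groupby(["frame", "camera_id"], sort=True):
            img_id = len(images) + 1
            image_ids[(frame, cam)] = img_id
            images.append({
                "id": img_id,
                "file_name": f"{cam}/{int(frame):06d}.jpg",
                "frame": int(frame),
                "camera_id": str(cam),
                "width": int(image_size[0]),
                "height": int(image_size[1]),
            })
            kps, scores = [], []
            by_lm = {r.landmark: r for r in grp.itertuples()}
            for name in names:
                rec = by_lm.get(name)
                if rec is None:
                    kps.extend([0.0, 0.0, 0])
                    scores.append(0.0)
                else:
                    kps.extend([float(rec.x), float(rec.y), 2])
                    scores.append(float(rec.confidence))
            source = grp["source"].iloc[0]
            annotations.append({
                "id": img_id,
                "image_id": img_id,
                "category_id": 1,
                "keypoints": kps,
                "scores": scores,
                "num_keypoints": int(sum(v > 0 for v in kps[2::3])),
                "source": str(source),
            })
        return {
            "images": images,
            "annotations": annotations,
            "categories": [{"id": 1, "name": "macaque", "keypoints": names, "skeleton": []}],
        }

    @classmethod
    def from_coco(cls, coco: dict) -> "DetectionSet":
        names = coco["categories"][0]["keypoints"]
        img_by_id = {im["id"]: im for im in coco["images"]}
        rows = []
        for ann in coco["annotations"]:
            im = img_by_id[ann["image_id"]]
            kps = ann["keypoints"]
            scores = ann.get("scores", [1.0] * len(names))
            for j, name in enumerate(names):
                x, y, v = kps[3 * j], kps[3 * j + 1], kps[3 * j + 2]
                if v > 0:
                    rows.append({
                        "frame": int(im["frame"]), "camera_id": str(im["camera_id"]),
                        "landmark": name, "x": float(x), "y": float(y),
                        "confidence": float(scores[j]), "source": ann.get("source", "detector"),
                    })
        return cls(pd.DataFrame(rows, columns=_DETECTION_COLUMNS))

    def save_coco(self, path, landmark_names: Sequence[str], image_size=(1280, 1024)) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_coco(landmark_names, image_size), fh)

    @classmethod
    def load_coco(cls, path) -> "DetectionSet":
        with open(path) as fh:
            return cls.from_coco(json.load(fh))


# ---------------------------------------------------------------------------
# Pose sequences
# ---------------------------------------------------------------------------

@dataclass
class PoseSequence3D:
    """Per-frame 3D landmark positions in meters with validity flags."""

    positions: np.ndarray        # (T, L, 3) float; NaN where invalid
    valid: np.ndarray            # (T, L) bool
    landmark_names: tuple[str, ...]
    fps: float = 30.0
    stage: str = "raw"           # {"ground_truth", "raw", "refined"}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.positions.shape[:2] != self.valid.shape or self.positions.shape[2] != 3:
            raise ValueError("positions must be (T, L, 3) matching valid (T, L)")
        self.landmark_names = tuple(self.landmark_names)
        if self.positions.shape[1] != len(self.landmark_names):
            raise ValueError("landmark axis does not match landmark_names")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def landmark(self, name: str) -> np.ndarray:
        """(T, 3) trajectory of one landmark (NaN where invalid)."""
        j = self.landmark_names.index(name)
        out = self.positions[:, j, :].copy()
        out[~self.valid[:, j]] = np.nan
        return out

    def centroid(self) -> np.ndarray:
        """(T, 3) per-frame centroid over valid landmarks."""
        pts = np.where(self.valid[:, :, None], self.positions, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(pts, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        T, L, _ = self.positions.shape
        frames = np.repeat(np.arange(T), L)
        lms = np.tile(np.array(self.landmark_names, dtype=object), T)
        flat = self.positions.reshape(T * L, 3)
        return pd.DataFrame({
            "frame": frames, "landmark": lms,
            "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2],
            "valid": self.valid.reshape(-1), "stage": self.stage,
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float = 30.0) -> "PoseSequence3D":
        names = tuple(dict.fromkeys(df["landmark"]))
        frames = np.sort(df["frame"].unique())
        T, L = len(frames), len(names)
        pos = np.full((T, L, 3), np.nan)
        val = np.zeros((T, L), dtype=bool)
        fidx = {f: i for i, f in enumerate(frames)}
        lidx = {n: j for j, n in enumerate(names)}
        for r in df.itertuples():
            i, j = fidx[r.frame], lidx[r.landmark]
            pos[i, j] = (r.x, r.y, r.z)
            val[i, j] = bool(r.valid)
        stage = df["stage"].iloc[0] if "stage" in df else "raw"
        return cls(pos, val, names, fps=fps, stage=str(stage))

    @classmethod
    def load_csv(cls, path, fps: float = 30.0) -> "PoseSequence3D":
        return cls.from_dataframe(pd.read_csv(path), fps=fps)


@dataclass
class ActionLabels:
    """Per-frame categorical action labels from the fixed vocabulary."""

    labels: np.ndarray   # (T,) array of strings
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(ACTIONS)
        if bad:
            raise ValueError(f"unknown action labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.labels)), "label": self.labels})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, fps: float = 30.0) -> "ActionLabels":
        df = pd.read_csv(path)
        return cls(df["label"].to_numpy(dtype=object), fps=fps)


@dataclass
class LimbLengths:
    """Estimated per-edge limb lengths in meters, keyed (parent, child)."""

    length: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for edge, val in self.length.items():
            if not val > 0:
                raise ValueError(f"limb length for {edge} must be positive")

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return self.length[edge]

    def as_vector(self, skeleton: Skeleton) -> np.ndarray:
        return np.array([self.length[e] for e in skeleton.edges])
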