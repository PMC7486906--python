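"""Synthetic multi-camera studio: rig, motion, detections, response maps.

Everything the physical system records is emulated here so the full
pipeline can be exercised end to end without image data or a trained
detector:

* :func:`make_rig` — a two-level ring of 62 inward-facing calibrated
  cameras around a 2.45 x 2.45 x 2.75 m enclosure;
* :func:`simulate_motion` — an articulated 13-landmark skeleton executing
  scripted actions (sit, stand, walk, climb, climb_supine, jump) with
  exactly conserved limb lengths;
* :func:`emulate_detections` — noisy per-view 2D landmark detections with
  Gaussian pixel noise, gross outliers, misses and view-dependent
  self-occlusion by a torso capsule;
* :func:`emulate_centroids` — per-view body centroids (stand-in for
  background-subtraction segmentation centers);
* :func:`render_response_map` — detector-style Gaussian response maps on
  the 46 x 46 grid of a 368 x 368 crop.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .camera_geometry import CameraModel, look_at_rotation, project_points
from .core import ACTIONS, ActionLabels, DetectionSet, PoseSequence3D, Skeleton

__all__ = [
    "RigSpec", "MotionScript", "MotionSegment", "NoiseModel",
    "make_rig", "simulate_motion", "emulate_detections", "emulate_centroids",
    "render_response_map", "stack_response_maps",
    "TORSO_RADIUS_M",
]

#: Radius of the neck-hip torso capsule used for self-occlusion, meters.
TORSO_RADIUS_M = 0.12

#: Gravitational acceleration used by the ballistic jump primitive, m/s^2.
GRAVITY = 9.81


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigSpec:
    """Geometry of the camera rig around the enclosure."""

    enclosure: tuple[float, float, float] = (2.45, 2.45, 2.75)
    n_cameras: int = 62
    n_levels: int = 2
    corner_angle: float = 45.0       # degrees; azimuth of the first camera per ring
    margin_m: float = 0.15           # ring stand-off outside the walls
    focal_px: float = 450.0
    image_size: tuple[int, int] = (1280, 1024)

    def __post_init__(self) -> None:
        if self.n_cameras < 2:
            raise ValueError("rig needs at least 2 cameras")
        if any(e <= 0 for e in self.enclosure):
            raise ValueError("enclosure extents must be positive")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


@dataclass(frozen=True)
class MotionSegment:
    action: str
    duration_s: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}; expected one of {ACTIONS}")
        if not self.duration_s > 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class MotionScript:
    """Ordered list of (action, duration) segments at a fixed frame rate."""

    segments: tuple[MotionSegment, ...]
    fps: float = 30.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script must contain at least one segment")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, float]], fps: float = 30.0) -> "MotionScript":
        return cls(tuple(MotionSegment(a, d) for a, d in pairs), fps=fps)


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise process emulating an imperfect landmark detector.

    Occluded landmarks are dropped (miss) by default; with
    ``occluded_sigma`` set they are instead reported with that inflated
    pixel noise, emulating a detector that hallucinates occluded joints.
    """

    pixel_sigma: float = 1.0
    outlier_prob: float = 0.0
    miss_prob: float = 0.0
    occlusion: bool = False
    occluded_sigma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sigma < 0:
            raise ValueError("pixel_sigma must be >= 0")
        for p in (self.outlier_prob, self.miss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Rig
# ---------------------------------------------------------------------------

def make_rig(spec: RigSpec = RigSpec()) -> list[CameraModel]:
    """Build the multi-camera rig: evenly spaced cameras on horizontal rings.

    Cameras sit on ``n_levels`` rings just outside the enclosure walls and
    all point at the enclosure center.  Ring azimuths start at
    ``corner_angle`` (so corner-facing cameras exist on a square enclosure)
    and alternate levels are staggered by half a spacing for coverage.
    Deterministic: no randomness involved.
    """
    ex, ey, ez = spec.enclosure
    radius = float(np.hypot(ex, ey)) / 2.0 + spec.margin_m
    target = np.array([0.0, 0.0, ez / 2.0])
    counts = [spec.n_cameras // spec.n_levels] * spec.n_levels
    for i in range(spec.n_cameras % spec.n_levels):
        counts[i] += 1
    w, h = spec.image_size
    cams: list[CameraModel] = []
    idx = 0
    for level, n_l in enumerate(counts):
        if n_l == 0:
            continue
        height = ez * (2 * level + 1) / (2 * spec.n_levels)
        spacing = 360.0 / n_l
        offset = spec.corner_angle + (spacing / 2.0 if level % 2 else 0.0)
        for j in range(n_l):
            az = np.radians(offset + j * spacing)
            center = np.array([radius * np.cos(az), radius * np.sin(az), height])
            R = look_at_rotation(center, target)
            cams.append(CameraModel(
                camera_id=f"cam{idx:02d}",
                focal=(spec.focal_px, spec.focal_px),
                principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
                rotation=R,
                translation=-R @ center,
                distortion=(0.0, 0.0),
                image_size=(w, h),
            ))
            idx += 1
    return cams


# ---------------------------------------------------------------------------
# Motion templates (body frame: f forward, r right, u up; offsets from neck, m)
# ---------------------------------------------------------------------------

def _tpl(**kw) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in kw.items()}


# Quadrupedal template used by walk.
_WALK = _tpl(
    neck=(0, 0, 0), head=(0.06, 0, 0.065), nose=(0.135, 0, 0.037),
    left_shoulder=(0.02, -0.10, -0.01), right_shoulder=(0.02, 0.10, -0.01),
    left_hand=(0.07, -0.11, -0.28), right_hand=(0.07, 0.11, -0.28),
    hip=(-0.32, 0, 0.0),
    left_knee=(-0.30, -0.09, -0.13), right_knee=(-0.30, 0.09, -0.13),
    left_foot=(-0.34, -0.09, -0.30), right_foot=(-0.34, 0.09, -0.30),
    tail=(-0.54, 0, 0.09),
)

# Bipedal upright stance: hands hang alongside the (near-vertical) torso,
# which is what makes the contralateral hand self-occluded from the far side.
_STAND = _tpl(
    neck=(0, 0, 0), head=(0.035, 0, 0.082), nose=(0.11, 0, 0.057),
    left_shoulder=(0.01, -0.10, -0.005), right_shoulder=(0.01, 0.10, -0.005),
    left_hand=(0.02, -0.12, -0.284), right_hand=(0.02, 0.12, -0.284),
    hip=(-0.055, 0, -0.315),
    left_knee=(-0.005, -0.085, -0.435), right_knee=(-0.005, 0.085, -0.435),
    left_foot=(0.025, -0.085, -0.612), right_foot=(0.025, 0.085, -0.612),
    tail=(-0.115, 0, -0.555),
)

_SIT = _tpl(
    neck=(0, 0, 0), head=(0.03, 0, 0.084), nose=(0.108, 0, 0.066),
    left_shoulder=(0.01, -0.10, -0.005), right_shoulder=(0.01, 0.10, -0.005),
    left_hand=(0.14, -0.12, -0.252), right_hand=(0.14, 0.12, -0.252),
    hip=(-0.13, 0, -0.292),
    left_knee=(0.005, -0.085, -0.282), right_knee=(0.005, 0.085, -0.282),
    left_foot=(0.085, -0.085, -0.443), right_foot=(0.085, 0.085, -0.443),
    tail=(-0.30, 0, -0.475),
)

_CLIMB = _tpl(
    neck=(0, 0, 0), head=(0.04, 0, 0.08), nose=(0.11, 0, 0.119),
    left_shoulder=(0.02, -0.10, 0.0), right_shoulder=(0.02, 0.10, 0.0),
    left_hand=(0.14, -0.13, 0.251), right_hand=(0.14, 0.13, 0.251),
    hip=(-0.066, 0, -0.313),
    left_knee=(0.034, -0.085, -0.403), right_knee=(0.034, 0.085, -0.403),
    left_foot=(0.164, -0.085, -0.527), right_foot=(0.164, 0.085, -0.527),
    tail=(-0.166, 0, -0.542),
)

_CLIMB_SUPINE = _tpl(
    neck=(0, 0, 0), head=(0.055, 0, -0.071), nose=(0.115, 0, -0.124),
    left_shoulder=(0.02, -0.098, 0.0), right_shoulder=(0.02, 0.098, 0.0),
    left_hand=(0.07, -0.118, 0.275), right_hand=(0.07, 0.118, 0.275),
    hip=(-0.313, 0, 0.066),
    left_knee=(-0.263, -0.085, 0.192), right_knee=(-0.263, 0.085, 0.192),
    left_foot=(-0.243, -0.085, 0.371), right_foot=(-0.243, 0.085, 0.371),
    tail=(-0.543, 0, -0.032),
)

_JUMP = _tpl(
    neck=(0, 0, 0), head=(0.05, 0, 0.075), nose=(0.127, 0, 0.055),
    left_shoulder=(0.02, -0.10, -0.005), right_shoulder=(0.02, 0.10, -0.005),
    left_hand=(0.26, -0.12, -0.148), right_hand=(0.26, 0.12, -0.148),
    hip=(-0.30, 0, -0.112),
    left_knee=(-0.40, -0.085, -0.202), right_knee=(-0.40, 0.085, -0.202),
    left_foot=(-0.54, -0.085, -0.315), right_foot=(-0.54, 0.085, -0.315),
    tail=(-0.52, 0, 0.006),
)

_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "sit": _SIT, "stand": _STAND, "walk": _WALK,
    "climb": _CLIMB, "climb_supine": _CLIMB_SUPINE, "jump": _JUMP,
}

#: Neck height above the floor per action (meters).
_NECK_Z = {"sit": 0.60, "stand": 0.70, "walk": 0.47,
           "climb": None, "climb_supine": 2.32, "jump": None}

_GAIT_HZ = 2.0          # stride frequency while walking
_WALK_SPEED = 0.42      # m/s
_SUPINE_SPEED = 0.20    # m/s traverse speed while hanging
_XY_BOUND = 0.80        # root horizontal bound keeping limbs inside walls


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _smooth_noise(rng: np.random.Generator, shape: tuple, sigma: float, alpha: float = 0.2) -> np.ndarray:
    """Temporally smoothed Gaussian noise (exponential moving average)."""
    white = rng.normal(0.0, sigma, size=shape)
    out = np.empty_like(white)
    acc = white[0]
    for i in range(shape[0]):
        acc = (1 - alpha) * acc + alpha * white[i]
        out[i] = acc
    return out


def _segment_root(action: str, n: int, dt: float, state: dict, rng: np.random.Generator,
                  bound: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame neck positions (n, 3) and headings (n,) for one segment."""
    xy = np.array(state["xy"], dtype=float)
    phi = float(state["phi"])
    roots = np.empty((n, 3))
    phis = np.empty(n)

    if action in ("sit", "stand"):
        drift = _smooth_noise(rng, (n,), 0.04)
        z0 = _NECK_Z[action]
        for i in range(n):
            phi = _wrap_angle(phi + drift[i] * 0.2)
            roots[i] = (xy[0], xy[1], z0)
            phis[i] = phi

    elif action in ("walk", "climb_supine"):
        speed = _WALK_SPEED if action == "walk" else _SUPINE_SPEED
        b = bound if action == "walk" else 0.65
        noise = rng.normal(0.0, 0.05, size=n)
        for i in range(n):
            r = max(abs(xy[0]), abs(xy[1]))
            steer = 0.0
            if r > 0.55:
                phi_center = np.arctan2(-xy[1], -xy[0])
                steer = 0.25 * _wrap_angle(phi_center - phi) * min(1.0, (r - 0.55) / 0.25)
            phi = _wrap_angle(phi + noise[i] + steer)
            xy = np.clip(xy + speed * dt * np.array([np.cos(phi), np.sin(phi)]), -b, b)
            if action == "walk":
                z = _NECK_Z["walk"] + 0.015 * np.sin(2 * np.pi * _GAIT_HZ * 2 * i * dt)
            else:
                z = _NECK_Z["climb_supine"]
            roots[i] = (xy[0], xy[1], z)
            phis[i] = phi

    elif action == "climb":
        # climb the nearest wall: glide to an inset anchor, then oscillate in z
        walls = [(np.array([0.925, np.clip(xy[1], -0.7, 0.7)]), 0.0),
                 (np.array([np.clip(xy[0], -0.7, 0.7), 0.925]), np.pi / 2),
                 (np.array([-0.925, np.clip(xy[1], -0.7, 0.7)]), np.pi),
                 (np.array([np.clip(xy[0], -0.7, 0.7), -0.925]), -np.pi / 2)]
        dists = [np.linalg.norm(a - xy) for a, _ in walls]
        anchor, phi_wall = walls[int(np.argmin(dists))]
        n_glide = min(n, max(1, int(round(0.6 / dt))))
        z_start = 1.05
        for i in range(n):
            if i < n_glide:
                w = (i + 1) / n_glide
                pos = (1 - w) * xy + w * anchor
                z = (1 - w) * float(state["z"]) + w * z_start
                phi = _wrap_angle(phi + w * _wrap_angle(phi_wall - phi))
            else:
                pos = anchor
                tt = (i - n_glide) * dt
                z = 1.55 + 0.50 * np.sin(2 * np.pi * tt / 6.0 - np.pi / 2)
                phi = phi_wall
            roots[i] = (pos[0], pos[1], z)
            phis[i] = phi
        xy = roots[-1, :2].copy()

    elif action == "jump":
        # consecutive ballistic arcs toward the enclosure center
        z_floor = _NECK_Z["walk"]
        i = 0
        while i < n:
            arc_frames = min(n - i, max(2, int(round(0.9 / dt))))
            d = arc_frames * dt
            vz = GRAVITY * d / 2.0
            target = rng.uniform(-0.4, 0.4, size=2)
            direction = target - xy
            dist = np.linalg.norm(direction)
            vxy = (direction / dist * min(1.6, dist / d)) if dist > 1e-9 else np.zeros(2)
            phi = float(np.arctan2(vxy[1], vxy[0])) if np.linalg.norm(vxy) > 1e-9 else phi
            for k in range(arc_frames):
                tau = (k + 1) * dt
                pos = xy + vxy * tau
                z = z_floor + vz * tau - 0.5 * GRAVITY * tau ** 2
                roots[i + k] = (pos[0], pos[1], max(z, z_floor))
                phis[i + k] = phi
            xy = roots[i + arc_frames - 1, :2].copy()
            i += arc_frames

    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown action {action!r}")

    state["xy"] = tuple(roots[-1, :2])
    state["phi"] = float(phis[-1])
    state["z"] = float(roots[-1, 2])
    return roots, phis


def _gait_offsets(tpl: dict[str, np.ndarray], action: str, t: float) -> dict[str, np.ndarray]:
    """Template with periodic limb swing applied (walking gait)."""
    if action != "walk":
        return tpl
    swing = 0.10 * np.sin(2 * np.pi * _GAIT_HZ * t)
    out = dict(tpl)
    for name, sign in (("left_hand", 1.0), ("right_hand", -1.0),
                       ("left_foot", -1.0), ("right_foot", 1.0)):
        out[name] = tpl[name] + np.array([sign * swing, 0.0, 0.0])
    return out


def simulate_motion(
    skeleton: Skeleton,
    script: MotionScript,
    seed: int = 0,
    enclosure: tuple[float, float, float] = (2.45, 2.45, 2.75),
) -> tuple[PoseSequence3D, ActionLabels]:
    """Simulate a scripted 13-landmark trajectory with exact limb lengths.

    Each action is a parameterized primitive (quasi-static sit/stand,
    periodic quadrupedal walk, vertical wall climb, inverted ceiling
    traverse, ballistic jump with g = 9.81 m/s^2).  Child landmarks are
    placed at parent + rest_length * unit(direction), so per-frame limb
    lengths equal the skeleton's rest lengths exactly.  Reproducible given
    the seed.
    """
    required = set(_WALK)
    missing = required - set(skeleton.landmark_names)
    if missing:
        raise ValueError(f"motion templates require landmarks {sorted(missing)}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / script.fps
    state = {"xy": (0.0, 0.0), "phi": float(rng.uniform(-np.pi, np.pi)), "z": 0.5}

    all_roots, all_phis, all_labels, all_actions = [], [], [], []
    for seg in script.segments:
        n = max(1, int(round(seg.duration_s * script.fps)))
        roots, phis = _segment_root(seg.action, n, dt, state, rng, _XY_BOUND)
        # ease the neck between segments (except into a jump, whose arc is exact)
        if all_roots and seg.action != "jump":
            prev = all_roots[-1][-1]
            k = min(n, int(round(0.5 * script.fps)))
            for i in range(k):
                w = (i + 1) / k
                roots[i] = (1 - w) * prev + w * roots[i]
        all_roots.append(roots)
        all_phis.append(phis)
        all_labels.extend([seg.action] * n)
        all_actions.append((seg.action, n))

    roots = np.concatenate(all_roots)
    phis = np.concatenate(all_phis)
    T = len(roots)
    L = skeleton.n_landmarks
    jitter = _smooth_noise(rng, (T, L, 3), 0.015)

    order = skeleton.bfs_order()
    name_to_idx = {n: j for j, n in enumerate(skeleton.landmark_names)}
    positions = np.empty((T, L, 3))
    t_global = 0
    for action, n in all_actions:
        tpl_base = _TEMPLATES[action]
        # keep every landmark above the floor and below the ceiling even
        # while the neck eases between action heights
        drop = min(v[2] for v in tpl_base.values())
        rise = max(v[2] for v in tpl_base.values())
        lo, hi = -drop + 0.06, enclosure[2] - rise - 0.06
        roots[t_global:t_global + n, 2] = np.clip(
            roots[t_global:t_global + n, 2], lo, hi)
        for i in range(n):
            t = t_global + i
            tpl = _gait_offsets(tpl_base, action, i * dt)
            phi = phis[t]
            f = np.array([np.cos(phi), np.sin(phi), 0.0])
            r = np.array([np.sin(phi), -np.cos(phi), 0.0])
            u = np.array([0.0, 0.0, 1.0])
            B = np.stack([f, r, u], axis=1)     # body -> world
            positions[t, name_to_idx[skeleton.root]] = roots[t]
            for child in order[1:]:
                parent = skeleton.parent_of[child]
                length = skeleton.rest_limb_lengths[(parent, child)]
                d_body = tpl[child] - tpl[parent] + jitter[t, name_to_idx[child]]
                d_world = B @ d_body
                d_world /= np.linalg.norm(d_world)
                positions[t, name_to_idx[child]] = (
                    positions[t, name_to_idx[parent]] + length * d_world
                )
        t_global += n

    valid = np.ones((T, L), dtype=bool)
    poses = PoseSequence3D(positions, valid, skeleton.landmark_names,
                           fps=script.fps, stage="ground_truth")
    labels = ActionLabels(np.asarray(all_labels, dtype=object), fps=script.fps)
    return poses, labels


# ---------------------------------------------------------------------------
# Detection emulation
# ---------------------------------------------------------------------------

def _segment_point_params(P1, Q1, P2, Q2):
    """Closest-approach parameters between segments P1->Q1 and P2->Q2.

    Batched (Ericson's clamped closest-point algorithm).  Returns (s, t,
    distance) with s, t in [0, 1].
    """
    d1 = Q1 - P1
    d2 = Q2 - P2
    r = P1 - P2
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    fdot = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * fdot - c * e) / np.where(denom > 1e-12, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > 1e-12, (b * s + fdot) / np.where(e > 1e-12, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    # recompute s for clamped t
    s = np.where(np.abs(t - t_cl) > 0, np.clip((b * t_cl - c) / np.where(a > 1e-12, a, 1.0), 0, 1), s)
    p = P1 + s[..., None] * d1
    q = P2 + t_cl[..., None] * d2
    dist = np.linalg.norm(p - q, axis=-1)
    return s, t_cl, dist


def _occlusion_mask(camera: CameraModel, positions: np.ndarray,
                    neck: np.ndarray, hip: np.ndarray,
                    radius: float = TORSO_RADIUS_M) -> np.ndarray:
    """(T, L) mask: landmark hidden behind the torso capsule for this camera."""
    T, L, _ = positions.shape
    C = camera.center
    P1 = np.broadcast_to(C, (T, L, 3))
    Q1 = positions
    P2 = np.broadcast_to(neck[:, None, :], (T, L, 3))
    Q2 = np.broadcast_to(hip[:, None, :], (T, L, 3))
    s, _, dist = _segment_point_params(P1, Q1, P2, Q2)
    # landmarks sitting on/inside the capsule are body surface, never self-hidden
    _, _, lm_dist = _segment_point_params(
        positions, positions, P2, Q2)
    on_body = lm_dist <= radius * 1.05
    blocked = (dist < radius) & (s < 0.98)
    return blocked & ~on_body


def emulate_detections(
    gt_poses: PoseSequence3D,
    cameras: Sequence[CameraModel],
    noise: NoiseModel,
    skeleton: Skeleton | None = None,
) -> DetectionSet:
    """Emulate per-view landmark detections from ground-truth 3D poses.

    Per (frame, camera, landmark): with probability ``miss_prob`` nothing is
    emitted; otherwise with probability ``outlier_prob`` a uniform-random
    in-image pixel; otherwise the exact projection plus isotropic Gaussian
    noise.  With occlusion on, landmarks whose viewing ray grazes the
    neck-hip torso capsule before reaching them become misses (or noisy
    detections when ``occluded_sigma`` is set).  Landmarks behind a camera
    or projecting outside its image are never emitted.
    """
    names = list(gt_poses.landmark_names)
    neck = gt_poses.positions[:, names.index("neck"), :]
    hip = gt_poses.positions[:, names.index("hip"), :]
    rng = np.random.default_rng(noise.seed)
    T, L, _ = gt_poses.positions.shape

    frames_col, cam_col, lm_col, x_col, y_col, conf_col = [], [], [], [], [], []
    frame_idx = np.arange(T)
    for cam in cameras:
        pix, depth = project_points(cam, gt_poses.positions.reshape(-1, 3))
        pix = pix.reshape(T, L, 2)
        depth = depth.reshape(T, L)
        visible = (depth > 0) & cam.contains(pix) & gt_poses.valid
        if noise.occlusion:
            occluded = _occlusion_mask(cam, gt_poses.positions, neck, hip)
        else:
            occluded = np.zeros((T, L), dtype=bool)

        u_miss = rng.random((T, L))
        u_out = rng.random((T, L))
        gauss = rng.normal(0.0, 1.0, (T, L, 2))
        w, h = cam.image_size
        out_pix = np.stack([rng.uniform(0, w - 1, (T, L)), rng.uniform(0, h - 1, (T, L))], axis=-1)
        conf = rng.uniform(0.5, 1.0, (T, L))

        emit = visible & (u_miss >= noise.miss_prob)
        if noise.occluded_sigma is None:
            emit &= ~occluded
            sigma = np.full((T, L), noise.pixel_sigma)
        else:
            sigma = np.where(occluded, noise.occluded_sigma, noise.pixel_sigma)
        is_out = emit & (u_out < noise.outlier_prob)
        final = np.where(is_out[..., None], out_pix, pix + gauss * sigma[..., None])
        conf = np.where(is_out, rng.uniform(0.0, 0.5, (T, L)), conf)

        sel = np.nonzero(emit)
        frames_col.append(frame_idx[sel[0]])
        cam_col.append(np.full(len(sel[0]), cam.camera_id, dtype=object))
        lm_col.append(np.array(names, dtype=object)[sel[1]])
        x_col.append(final[sel][:, 0])
        y_col.append(final[sel][:, 1])
        conf_col.append(conf[sel])

    df = pd.DataFrame({
        "frame": np.concatenate(frames_col).astype(int),
        "camera_id": np.concatenate(cam_col),
        "landmark": np.concatenate(lm_col),
        "x": np.concatenate(x_col),
        "y": np.concatenate(y_col),
        "confidence": np.clip(np.concatenate(conf_col), 0.0, 1.0),
        "source": "detector",
    })
    df = df.sort_values(["frame", "camera_id", "landmark"], kind="stable").reset_index(drop=True)
    return DetectionSet(df)


def emulate_centroids(
    gt_poses: PoseSequence3D,
    cameras: Sequence[CameraModel],
    noise: NoiseModel,
) -> pd.DataFrame:
    """Per-frame per-camera 2D centroid of the projected body.

    The centroid of the projected landmark cloud stands in for the center
    of background-subtracted segmentation pixels.  Miss/outlier/noise
    semantics follow :func:`emulate_detections` (no occlusion: a body
    centroid is never self-occluded).
    """
    rng = np.random.default_rng(noise.seed)
    T, L, _ = gt_poses.positions.shape
    rows = {"frame": [], "camera_id": [], "x": [], "y": []}
    for cam in cameras:
        pix, depth = project_points(cam, gt_poses.positions.reshape(-1, 3))
        pix = pix.reshape(T, L, 2)
        depth = depth.reshape(T, L)
        ok = (depth > 0) & gt_poses.valid
        with np.errstate(invalid="ignore"):
            centroid = np.nansum(np.where(ok[..., None], pix, 0.0), axis=1) / \
                np.maximum(ok.sum(axis=1)[:, None], 1)
        any_vis = ok.any(axis=1)

        u_miss = rng.random(T)
        u_out = rng.random(T)
        gauss = rng.normal(0.0, noise.pixel_sigma, (T, 2))
        w, h = cam.image_size
        out_pix = np.stack([rng.uniform(0, w - 1, T), rng.uniform(0, h - 1, T)], axis=-1)

        emit = any_vis & (u_miss >= noise.miss_prob)
        is_out = emit & (u_out < noise.outlier_prob)
        final = np.where(is_out[:, None], out_pix, centroid + gauss)
        sel = np.nonzero(emit)[0]
        rows["frame"].extend(sel.tolist())
        rows["camera_id"].extend([cam.camera_id] * len(sel))
        rows["x"].extend(final[sel, 0].tolist())
        rows["y"].extend(final[sel, 1].tolist())
    df = pd.DataFrame(rows)
    return df.sort_values(["frame", "camera_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Response maps
# ---------------------------------------------------------------------------

def render_response_map(
    landmark_pixel_in_crop: tuple[float, float] | None,
    grid: int = 46,
    sigma_px: float = 8.0,
) -> np.ndarray:
    """Gaussian response map for one landmark on the detector output grid.

    The crop is ``8 * grid`` pixels square (368 for the default grid of
    46); cell (row, col) covers crop pixels [8*col, 8*col + 8) x
    [8*row, 8*row + 8).  Out-of-crop (or None) landmarks produce an
    all-zero map — the occluded-label convention.
    """
    size = 8 * grid
    out = np.zeros((grid, grid))
    if landmark_pixel_in_crop is None:
        return out
    x, y = float(landmark_pixel_in_crop[0]), float(landmark_pixel_in_crop[1])
    if not (0 <= x <= size - 1 and 0 <= y <= size - 1):
        return out
    u, v = x / 8.0, y / 8.0
    sigma_g = sigma_px / 8.0
    cc = np.arange(grid) + 0.5
    gx = np.exp(-((cc - u) ** 2) / (2 * sigma_g ** 2))
    gy = np.exp(-((cc - v) ** 2) / (2 * sigma_g ** 2))
    return gy[:, None] * gx[None, :]


def stack_response_maps(
    pixels: Mapping[str, tuple[float, float] | None],
    landmark_names: Sequence[str],
    grid: int = 46,
    sigma_px: float = 8.0,
) -> np.ndarray:
    """(grid, grid, L+1) stack: one channel per landmark plus background.

    The background channel is ``1 - max`` over the landmark channels,
    clipped at zero.
    """
    maps = [render_response_map(pixels.get(n), grid, sigma_px) for n in landmark_names]
    stack = np.stack(maps, axis=-1)
    background = np.clip(1.0 - stack.max(axis=-1), 0.0, None)
    return np.concatenate([stack, background[..., None]], axis=-1)
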