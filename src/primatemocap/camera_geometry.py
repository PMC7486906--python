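"""Camera models, projection and robust multiview triangulation.

A camera is a pinhole with two-term radial (Brown) distortion, a 3x3
world-to-camera rotation and a translation in meters.  Three triangulators
are provided:

* :func:`triangulate_dlt` — homogeneous direct-linear-transform least
  squares over all views (observations are undistorted first);
* :func:`triangulate_ransac` — pairwise hypothesize-and-verify consensus,
  exhaustive over all camera pairs for rigs up to 62 cameras (which removes
  sampling variance) and seeded random sampling beyond that;
* :func:`triangulate_meanshift` — mode seeking with a Gaussian kernel over
  the cloud of all pairwise two-view triangulations.

Pixel convention: 0-based, x right, y down, coordinates refer to pixel
centers.  World frame: meters, z up, origin at the enclosure floor center.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CameraModel", "Observation2D", "TriangulationResult",
    "GeometryError", "BehindCameraError", "InsufficientViewsError",
    "DegenerateGeometryError",
    "project", "project_points", "undistort_pixel", "pixel_to_ray",
    "triangulate_dlt", "triangulate_ransac", "triangulate_meanshift",
    "look_at_rotation", "viewing_angle_deg", "transform_camera",
    "load_calibration", "save_calibration",
]

#: Condition-number threshold above which the DLT system is treated as degenerate.
DLT_CONDITION_LIMIT = 1e8


class GeometryError(ValueError):
    """Base class for geometric failures."""


class BehindCameraError(GeometryError):
    """Point has non-positive depth in the camera frame."""


class InsufficientViewsError(GeometryError):
    """Fewer observations than the minimum required views."""


class DegenerateGeometryError(GeometryError):
    """Near-parallel rays: the DLT system is ill conditioned."""


# ---------------------------------------------------------------------------
# Camera model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """One calibrated camera: intrinsics, radial distortion and pose."""

    camera_id: str
    focal: tuple[float, float]                 # (fx, fy) pixels
    principal_point: tuple[float, float]       # (cx, cy) pixels
    rotation: np.ndarray                       # (3, 3) world -> camera
    translation: np.ndarray                    # (3,) meters
    distortion: tuple[float, float] = (0.0, 0.0)   # (k1, k2)
    image_size: tuple[int, int] = (1280, 1024)     # (width, height)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-9 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        fx, fy = self.focal
        if not (fx > 0 and fy > 0):
            raise ValueError("focal lengths must be positive")
        w, h = self.image_size
        if not (int(w) == w and int(h) == h and w > 0 and h > 0):
            raise ValueError("image_size must be positive integers")

    @property
    def center(self) -> np.ndarray:
        """Optical center in world coordinates."""
        return -self.rotation.T @ self.translation

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        """Whether pixel coordinates fall inside the image."""
        p = np.asarray(pixels, dtype=float)
        w, h = self.image_size
        return (p[..., 0] >= 0) & (p[..., 0] <= w - 1) & (p[..., 1] >= 0) & (p[..., 1] <= h - 1)


@dataclass(frozen=True)
class Observation2D:
    """A 2D pixel observation of one landmark in one camera."""

    camera_id: str
    pixel: tuple[float, float]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if not np.all(np.isfinite(self.pixel)):
            raise ValueError("pixel must be finite")


@dataclass
class TriangulationResult:
    """Robust triangulation output: the point, its inlier views and fit quality."""

    point: np.ndarray | None
    inlier_camera_ids: frozenset[str] = field(default_factory=frozenset)
    mean_reprojection_error: float = float("nan")

    @property
    def valid(self) -> bool:
        return self.point is not None and len(self.inlier_camera_ids) >= 2


# ---------------------------------------------------------------------------
# Projection / distortion
# ---------------------------------------------------------------------------

def _distort_normalized(xn: np.ndarray, k1: float, k2: float) -> np.ndarray:
    r2 = np.sum(xn ** 2, axis=-1, keepdims=True)
    return xn * (1.0 + k1 * r2 + k2 * r2 ** 2)


def project_points(camera: CameraModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project world points (..., 3) to pixels (..., 2); also return depths.

    Does not raise on non-positive depth — callers decide (pipelines treat
    behind-camera points as invisible, :func:`project` raises).
    """
    X = np.asarray(points, dtype=float)
    Xc = X @ camera.rotation.T + camera.translation
    depth = Xc[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = Xc[..., :2] / depth[..., None]
    xd = _distort_normalized(xn, *camera.distortion)
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    pix = np.stack([cx + fx * xd[..., 0], cy + fy * xd[..., 1]], axis=-1)
    return pix, depth


def project(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project a single world point to pixel coordinates.

    Raises :class:`BehindCameraError` if the point has non-positive depth.
    """
    pix, depth = project_points(camera, np.asarray(point, dtype=float).reshape(3))
    if depth <= 0:
        raise BehindCameraError(
            f"point has non-positive depth {depth:.4g} in camera {camera.camera_id!r}"
        )
    return pix


def undistort_pixel(camera: CameraModel, pixel: np.ndarray) -> np.ndarray:
    """Invert the radial distortion: distorted pixel(s) -> undistorted normalized coords.

    Fixed-point iteration (25 rounds), accurate to <1e-9 px for
    |k1|, |k2| <= 0.3 over the image domain.
    """
    p = np.asarray(pixel, dtype=float)
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    xd = np.stack([(p[..., 0] - cx) / fx, (p[..., 1] - cy) / fy], axis=-1)
    k1, k2 = camera.distortion
    if k1 == 0.0 and k2 == 0.0:
        return xd
    xn = xd.copy()
    for _ in range(25):
        r2 = np.sum(xn ** 2, axis=-1, keepdims=True)
        xn = xd / (1.0 + k1 * r2 + k2 * r2 ** 2)
    return xn


def pixel_to_ray(camera: CameraModel, pixel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World-frame ray (origin, unit direction) through a pixel."""
    xn = undistort_pixel(camera, pixel)
    d_cam = np.concatenate([xn, np.ones_like(xn[..., :1])], axis=-1)
    d_world = d_cam @ camera.rotation
    d_world = d_world / np.linalg.norm(d_world, axis=-1, keepdims=True)
    return camera.center, d_world


# ---------------------------------------------------------------------------
# Observation plumbing
# ---------------------------------------------------------------------------

def _as_pairs(observations) -> list[tuple[CameraModel, np.ndarray]]:
    """Normalize input to [(camera, pixel array)]."""
    out = []
    for cam, obs in observations:
        pix = np.asarray(obs.pixel if isinstance(obs, Observation2D) else obs, dtype=float)
        out.append((cam, pix.reshape(2)))
    return out


# ---------------------------------------------------------------------------
# DLT
# ---------------------------------------------------------------------------

def triangulate_dlt(observations, min_views: int = 2) -> np.ndarray:
    """Direct-linear-transform triangulation over all observations.

    Observations are undistorted to normalized coordinates before stacking
    the homogeneous linear system; the smallest-singular-vector solution is
    the least-squares point.  Raises :class:`InsufficientViewsError` with
    fewer than ``min_views`` observations and :class:`DegenerateGeometryError`
    when the design matrix is ill conditioned (near-parallel rays).
    """
    pairs = _as_pairs(observations)
    if len(pairs) < max(2, min_views):
        raise InsufficientViewsError(f"need >= {max(2, min_views)} views, got {len(pairs)}")
    stack = _CameraStack([c for c, _ in pairs])
    pixels = np.asarray([p for _, p in pairs])
    return _dlt_core(stack, pixels)


def _dlt_core(stack: "_CameraStack", pixels: np.ndarray) -> np.ndarray:
    """Vectorized homogeneous DLT over a camera stack."""
    xn = stack.normalized(pixels)                             # (k, 2)
    P = np.concatenate([stack.Rs, stack.ts[:, :, None]], axis=2)   # (k, 3, 4)
    rows = np.empty((2 * len(pixels), 4))
    rows[0::2] = xn[:, 0:1] * P[:, 2, :] - P[:, 0, :]
    rows[1::2] = xn[:, 1:2] * P[:, 2, :] - P[:, 1, :]
    _, s, vt = np.linalg.svd(rows)
    # the smallest singular value carries the solution; conditioning of the
    # remaining directions decides degeneracy
    if s[-2] <= 0 or s[0] / s[-2] > DLT_CONDITION_LIMIT:
        raise DegenerateGeometryError("near-parallel rays: DLT system ill conditioned")
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-15:
        raise DegenerateGeometryError("triangulated point at infinity")
    return Xh[:3] / Xh[3]


# ---------------------------------------------------------------------------
# Pairwise (two-view) candidates, vectorized
# ---------------------------------------------------------------------------

def _pairwise_candidates(
    centers: np.ndarray, dirs: np.ndarray, pair_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint triangulation for each ray pair.

    Returns (P, 3) candidate points and the ray-gap distance for each pair
    (used to reject near-parallel or skew configurations).
    """
    i, j = pair_idx[:, 0], pair_idx[:, 1]
    C1, C2 = centers[i], centers[j]
    d1, d2 = dirs[i], dirs[j]
    b = C2 - C1
    d1d2 = np.sum(d1 * d2, axis=1)
    denom = 1.0 - d1d2 ** 2
    bd1 = np.sum(b * d1, axis=1)
    bd2 = np.sum(b * d2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (bd1 - d1d2 * bd2) / denom
        u = (d1d2 * bd1 - bd2) / denom
    p1 = C1 + s[:, None] * d1
    p2 = C2 + u[:, None] * d2
    pts = 0.5 * (p1 + p2)
    gap = np.linalg.norm(p1 - p2, axis=1)
    bad = denom < 1e-12
    pts[bad] = np.nan
    gap[bad] = np.inf
    return pts, gap


class _CameraStack:
    """Stacked camera parameters for batched projection/ray computation."""

    def __init__(self, cameras: Sequence[CameraModel]):
        self.cameras = list(cameras)
        self.Rs = np.stack([c.rotation for c in cameras])             # (n, 3, 3)
        self.ts = np.stack([c.translation for c in cameras])          # (n, 3)
        self.Rflat = self.Rs.reshape(-1, 3)                           # (3n, 3)
        self.foc = np.asarray([c.focal for c in cameras])             # (n, 2)
        self.pp = np.asarray([c.principal_point for c in cameras])    # (n, 2)
        self.dist = np.asarray([c.distortion for c in cameras])       # (n, 2)
        self.centers = np.asarray([c.center for c in cameras])        # (n, 3)

    def sq_reprojection_errors(self, pixels: np.ndarray, points: np.ndarray) -> np.ndarray:
        """(n, P) squared pixel errors; inf where behind a camera."""
        n = len(self.cameras)
        Xc = (points @ self.Rflat.T).reshape(len(points), n, 3) + self.ts  # (P, n, 3)
        depth = Xc[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            xn = Xc[..., :2] / depth[..., None]
        r2 = np.sum(xn ** 2, axis=-1, keepdims=True)
        xd = xn * (1.0 + self.dist[None, :, 0:1] * r2 + self.dist[None, :, 1:2] * r2 ** 2)
        proj = self.pp + self.foc * xd                                 # (P, n, 2)
        d = proj - pixels[None, :, :]
        errs = d[..., 0] ** 2 + d[..., 1] ** 2
        errs[~np.isfinite(errs)] = np.inf
        errs[depth <= 0] = np.inf
        return errs.T

    def normalized(self, pixels: np.ndarray) -> np.ndarray:
        """(n, 2) undistorted normalized coordinates, one pixel per camera."""
        xd = (pixels - self.pp) / self.foc
        if not np.any(self.dist != 0.0):
            return xd
        k1, k2 = self.dist[:, 0:1], self.dist[:, 1:2]
        xn = xd.copy()
        for _ in range(25):
            r2 = np.sum(xn ** 2, axis=-1, keepdims=True)
            xn = xd / (1.0 + k1 * r2 + k2 * r2 ** 2)
        return xn

    def rays(self, pixels: np.ndarray) -> np.ndarray:
        """(n, 3) unit world-frame ray directions, one pixel per camera."""
        xn = self.normalized(pixels)
        d_cam = np.concatenate([xn, np.ones((len(xn), 1))], axis=-1)
        d_world = np.einsum("nji,nj->ni", self.Rs, d_cam)
        return d_world / np.linalg.norm(d_world, axis=-1, keepdims=True)

    def subset(self, idx: np.ndarray) -> "_CameraStack":
        """Lightweight view of a camera subset (shares no python-level loops)."""
        out = object.__new__(_CameraStack)
        out.cameras = [self.cameras[int(i)] for i in idx]
        out.Rs = self.Rs[idx]
        out.ts = self.ts[idx]
        out.Rflat = out.Rs.reshape(-1, 3)
        out.foc = self.foc[idx]
        out.pp = self.pp[idx]
        out.dist = self.dist[idx]
        out.centers = self.centers[idx]
        return out


def _reprojection_errors(
    cameras: Sequence[CameraModel], pixels: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """(n_cameras, n_points) pixel reprojection errors; inf where behind camera."""
    sq = _CameraStack(cameras).sq_reprojection_errors(pixels, points)
    return np.sqrt(sq)


# ---------------------------------------------------------------------------
# RANSAC
# ---------------------------------------------------------------------------

def triangulate_ransac(
    observations,
    inlier_threshold_px: float = 10.0,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> TriangulationResult:
    """Robust consensus triangulation from pairwise hypotheses.

    Every pair of views proposes a candidate 3D point (exhaustively for rigs
    up to 62 cameras, else ``n_iterations`` seeded random pairs); the
    candidate maximizing the number of views with reprojection error below
    ``inlier_threshold_px`` wins (ties: lower mean inlier error, then first
    pair in enumeration order).  The final point is a DLT fit over the
    winning inlier set.  Returns an invalid result when no candidate gains
    at least two inliers.
    """
    pairs = _as_pairs(observations)
    if len(pairs) < 2:
        raise InsufficientViewsError(f"need >= 2 views, got {len(pairs)}")
    stack = _CameraStack([c for c, _ in pairs])
    pixels = np.asarray([p for _, p in pairs])
    return _ransac_core(stack, pixels, inlier_threshold_px, n_iterations, seed)


def _ransac_core(stack: "_CameraStack", pixels: np.ndarray,
                 inlier_threshold_px: float, n_iterations: int | None = None,
                 seed: int | None = None) -> TriangulationResult:
    dirs = stack.rays(pixels)
    n = len(pixels)
    all_pairs = np.asarray(list(itertools.combinations(range(n), 2)))
    if n <= 62 or n_iterations is None or n_iterations >= len(all_pairs):
        pair_idx = all_pairs
    else:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(all_pairs), size=n_iterations, replace=False)
        pair_idx = all_pairs[np.sort(pick)]

    cand, _gap = _pairwise_candidates(stack.centers, dirs, pair_idx)
    ok = np.isfinite(cand).all(axis=1)
    if not ok.any():
        return TriangulationResult(None)
    cand = cand[ok]

    thr2 = inlier_threshold_px ** 2
    sq = stack.sq_reprojection_errors(pixels, cand)           # (n, P)
    inlier = sq < thr2
    counts = inlier.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_err = np.where(counts > 0, np.sum(np.where(inlier, sq, 0.0), axis=0)
                            / np.maximum(counts, 1), np.inf)
    order = np.lexsort((np.arange(len(cand)), mean_err, -counts))
    best = order[0]
    if counts[best] < 2:
        return TriangulationResult(None)

    inlier_idx = np.flatnonzero(inlier[:, best])
    try:
        point = _dlt_core(stack.subset(inlier_idx), pixels[inlier_idx])
    except GeometryError:
        return TriangulationResult(None)
    final_sq = stack.sq_reprojection_errors(pixels, point[None, :])[:, 0]
    final_inliers = final_sq < thr2
    if final_inliers.sum() < 2:
        return TriangulationResult(None)
    ids = frozenset(stack.cameras[k].camera_id for k in np.flatnonzero(final_inliers))
    return TriangulationResult(
        point=point,
        inlier_camera_ids=ids,
        mean_reprojection_error=float(np.sqrt(final_sq[final_inliers]).mean()),
    )


# ---------------------------------------------------------------------------
# Mean shift
# ---------------------------------------------------------------------------

def triangulate_meanshift(
    observations, bandwidth_m: float = 0.05, max_iter: int = 200, tol: float = 1e-10
) -> np.ndarray:
    """Mode-seeking triangulation over the pairwise candidate cloud.

    All camera pairs are triangulated (midpoint method); mean shift with a
    Gaussian kernel of the given bandwidth then climbs to the densest mode,
    starting from the candidate of highest kernel density.  In the
    ``bandwidth -> inf`` limit the result is the mean of all candidates.
    """
    pairs = _as_pairs(observations)
    if len(pairs) < 2:
        raise InsufficientViewsError(f"need >= 2 views, got {len(pairs)}")
    centers = np.asarray([c.center for c, _ in pairs])
    dirs = np.asarray([pixel_to_ray(c, p)[1] for c, p in pairs])
    pair_idx = np.asarray(list(itertools.combinations(range(len(pairs)), 2)))
    cand, _ = _pairwise_candidates(centers, dirs, pair_idx)
    cand = cand[np.isfinite(cand).all(axis=1)]
    if len(cand) == 0:
        raise DegenerateGeometryError("no finite pairwise candidates")

    inv_2h2 = 0.0 if np.isinf(bandwidth_m) else 1.0 / (2.0 * bandwidth_m ** 2)

    def weights(x: np.ndarray) -> np.ndarray:
        d2 = np.sum((cand - x) ** 2, axis=1)
        return np.exp(-d2 * inv_2h2)

    density = [weights(c).sum() for c in cand]
    x = cand[int(np.argmax(density))].copy()
    for _ in range(max_iter):
        w = weights(x)
        x_new = (w[:, None] * cand).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    return x


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def look_at_rotation(center: np.ndarray, target: np.ndarray, up=(0.0, 0.0, 1.0)) -> np.ndarray:
    """World->camera rotation for a camera at ``center`` looking at ``target``.

    Camera axes: x right, y down, z forward (optical axis toward target).
    """
    f = np.asarray(target, dtype=float) - np.asarray(center, dtype=float)
    f = f / np.linalg.norm(f)
    upv = np.asarray(up, dtype=float)
    x = np.cross(f, upv)
    nx = np.linalg.norm(x)
    if nx < 1e-12:   # looking straight along up: pick an arbitrary right vector
        x = np.cross(f, np.array([1.0, 0.0, 0.0]))
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(f, x)   # points "down" when up is world-up
    y = y / np.linalg.norm(y)
    # rows of R are the camera axes expressed in world coordinates
    R = np.stack([x, y, f])
    # re-orthonormalize to keep ||R^T R - I|| < 1e-9 exactly
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = -R
    return R


def viewing_angle_deg(baseline_m: float, distance_m: float) -> float:
    """Angle subtended at a subject by two cameras ``baseline_m`` apart.

    For adjacent cameras 0.35 m apart viewing a subject 3 m away this is
    about 6.7 degrees — the rig design bound on view difference.
    """
    ratio = min(1.0, baseline_m / (2.0 * distance_m))
    return float(np.degrees(2.0 * np.arcsin(ratio)))


def transform_camera(camera: CameraModel, R0: np.ndarray, t0: np.ndarray) -> CameraModel:
    """Apply a global rigid transform X -> R0 X + t0 to the world frame."""
    R0 = np.asarray(R0, dtype=float)
    t0 = np.asarray(t0, dtype=float).reshape(3)
    R_new = camera.rotation @ R0.T
    t_new = camera.translation - R_new @ t0
    return CameraModel(
        camera_id=camera.camera_id, focal=camera.focal,
        principal_point=camera.principal_point, rotation=R_new,
        translation=t_new, distortion=camera.distortion,
        image_size=camera.image_size,
    )


# ---------------------------------------------------------------------------
# Calibration JSON
# ---------------------------------------------------------------------------

def _camera_to_dict(cam: CameraModel) -> dict:
    fx, fy = cam.focal
    cx, cy = cam.principal_point
    return {
        "camera_id": cam.camera_id,
        "K": [[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]],
        "dist": list(cam.distortion),
        "R": cam.rotation.tolist(),
        "t": cam.translation.tolist(),
        "image_size": list(cam.image_size),
    }


def _camera_from_dict(d: dict) -> CameraModel:
    K = np.asarray(d["K"], dtype=float)
    return CameraModel(
        camera_id=str(d["camera_id"]),
        focal=(float(K[0, 0]), float(K[1, 1])),
        principal_point=(float(K[0, 2]), float(K[1, 2])),
        rotation=np.asarray(d["R"], dtype=float),
        translation=np.asarray(d["t"], dtype=float),
        distortion=tuple(float(v) for v in d.get("dist", (0.0, 0.0)))[:2] or (0.0, 0.0),
        image_size=tuple(int(v) for v in d.get("image_size", (1280, 1024))),
    )


def save_calibration(path, cameras: Sequence[CameraModel]) -> None:
    with open(path, "w") as fh:
        json.dump([_camera_to_dict(c) for c in cameras], fh, indent=1)


def load_calibration(path) -> list[CameraModel]:
    """Load and validate a calibration JSON file (list of cameras)."""
    with open(path) as fh:
        data = json.load(fh)
    return [_camera_from_dict(d) for d in data]
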