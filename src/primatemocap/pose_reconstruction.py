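"""Inference-time 3D pose reconstruction and physically plausible refinement.

The reconstruction stage turns per-view detector outputs into 3D landmark
trajectories:

1. :func:`decode_response_maps` — argmax decoding of detector response
   maps back to full-image pixel coordinates;
2. :func:`reconstruct_sequence` — per-frame, per-landmark robust RANSAC
   triangulation (each landmark independently);
3. :func:`estimate_limb_lengths` — per-edge median distance over time,
   the subject-specific limb lengths;
4. :func:`refine_chain` — recursive refinement along the kinematic chain:
   for each landmark X_t the objective

       sum_i ||Pi_i(X_t) - x_{i,t}||^2
       + w_L (||X_t - Y_t|| - L_{X,Y})^2
       + w_T ||X_{t-1} - X_t||^2

   (reprojection consistency, limb-length constraint to the parent Y_t,
   temporal smoothness) is minimized by quasi-Newton (BFGS, gradient
   threshold 1e-5) starting from the raw triangulation, sweeping frames
   forward with the root (neck) refined first and children after their
   parents.  The printed form of the objective is an unweighted sum; the
   weights default to 1 and are exposed because the pixel^2 and meter^2
   terms are dimensionally heterogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .annotation_pipeline import CropWindow
from .camera_geometry import CameraModel, Observation2D, _CameraStack, _ransac_core
from .core import DetectionSet, LimbLengths, PoseSequence3D, Skeleton

__all__ = [
    "decode_response_maps", "reconstruct_sequence",
    "estimate_limb_lengths", "refine_chain", "RefineDiagnostics",
]


# ---------------------------------------------------------------------------
# Response-map decoding
# ---------------------------------------------------------------------------

def _argmax_last(channel: np.ndarray) -> tuple[int, int]:
    """Argmax cell with ties broken toward the highest flat index.

    The renderer places the peak symmetrically when a landmark falls on a
    cell boundary; breaking toward the higher index keeps the decoded cell
    equal to the cell containing the landmark.
    """
    flat = channel.ravel()
    idx = len(flat) - 1 - int(np.argmax(flat[::-1]))
    return divmod(idx, channel.shape[1])


def decode_response_maps(
    stack: np.ndarray,
    crop: CropWindow,
    landmark_names: Sequence[str],
) -> dict[str, Observation2D | None]:
    """Decode a (46, 46, L+1) response stack to full-image observations.

    Per landmark channel the argmax cell (row r, col c) maps to crop pixel
    (8c + 4, 8r + 4) — the cell center — and then through the crop window
    back to full-image coordinates.  Confidence is the maximum response.
    An all-zero (or negative-free zero-max) channel means the landmark is
    missing in this view.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] < len(landmark_names):
        raise ValueError("stack must be (grid, grid, n_landmarks [+ background])")
    out: dict[str, Observation2D | None] = {}
    for j, name in enumerate(landmark_names):
        channel = stack[:, :, j]
        peak = float(channel.max())
        if peak <= 0.0:
            out[name] = None
            continue
        r, c = _argmax_last(channel)
        crop_px = np.array([8.0 * c + 4.0, 8.0 * r + 4.0])
        img = crop.crop_to_image(crop_px)
        out[name] = Observation2D(camera_id=crop.camera_id,
                                  pixel=(float(img[0]), float(img[1])),
                                  confidence=min(1.0, peak))
    return out


# ---------------------------------------------------------------------------
# Sequence reconstruction
# ---------------------------------------------------------------------------

def reconstruct_sequence(
    detections: DetectionSet,
    cameras: Sequence[CameraModel],
    landmark_names: Sequence[str] | None = None,
    inlier_threshold_px: float = 10.0,
    fps: float = 30.0,
    seed: int = 0,
) -> PoseSequence3D:
    """RANSAC-triangulate every landmark of every frame independently.

    Landmarks seen by fewer than two cameras in a frame — or for which no
    consensus of at least two views exists — are flagged invalid, never
    fatal.
    """
    names = list(landmark_names) if landmark_names is not None else detections.landmarks
    cam_index = {c.camera_id: i for i, c in enumerate(cameras)}
    full_stack = _CameraStack(cameras)
    frames = detections.frames
    T = int(frames.max()) + 1 if len(frames) else 0
    L = len(names)
    positions = np.full((T, L, 3), np.nan)
    valid = np.zeros((T, L), dtype=bool)

    df = detections.df
    grouped = df.groupby(["frame", "landmark"], sort=True)
    name_to_j = {n: j for j, n in enumerate(names)}
    for (frame, landmark), grp in grouped:
        j = name_to_j.get(landmark)
        if j is None:
            continue
        idx = np.array([cam_index[c] for c in grp["camera_id"] if c in cam_index])
        if len(idx) < 2:
            continue
        pixels = grp[["x", "y"]].to_numpy(dtype=float)
        res = _ransac_core(full_stack.subset(idx), pixels, inlier_threshold_px,
                           None, seed)
        if res.valid:
            positions[int(frame), j] = res.point
            valid[int(frame), j] = True
    return PoseSequence3D(positions, valid, tuple(names), fps=fps, stage="raw")


# ---------------------------------------------------------------------------
# Limb lengths
# ---------------------------------------------------------------------------

def estimate_limb_lengths(poses: PoseSequence3D, skeleton: Skeleton) -> LimbLengths:
    """Median over time of the distance between connected landmarks.

    Raises if an edge is never co-valid (no frame with both endpoints
    reconstructed), naming the edge.
    """
    lengths: dict[tuple[str, str], float] = {}
    for parent, child in skeleton.edges:
        pi, ci = poses.landmark_names.index(parent), poses.landmark_names.index(child)
        both = poses.valid[:, pi] & poses.valid[:, ci]
        if not both.any():
            raise ValueError(f"edge ({parent}, {child}) has no frame with both endpoints valid")
        d = np.linalg.norm(poses.positions[both, ci] - poses.positions[both, pi], axis=1)
        lengths[(parent, child)] = float(np.median(d))
    return LimbLengths(lengths)


# ---------------------------------------------------------------------------
# Kinematic-chain refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineDiagnostics:
    """Per (frame, landmark) objective values before and after refinement."""

    objective_init: np.ndarray = field(default_factory=lambda: np.empty(0))
    objective_final: np.ndarray = field(default_factory=lambda: np.empty(0))


def _reprojection_term(sub: _CameraStack, pixels: np.ndarray, X: np.ndarray):
    """Sum of squared reprojection errors and its gradient wrt X.

    Cameras for which X has non-positive depth contribute a large constant
    (no useful gradient; the solver is repelled by the other terms).
    """
    Xc = sub.Rs @ X + sub.ts                           # (n, 3)
    z = Xc[:, 2]
    front = z > 1e-8
    if not front.any():
        return 1e12, np.zeros(3)
    Xc, z = Xc[front], z[front]
    Rs = sub.Rs[front]
    xn = Xc[:, :2] / z[:, None]
    r2 = np.sum(xn ** 2, axis=1, keepdims=True)
    k1 = sub.dist[front, 0:1]
    k2 = sub.dist[front, 1:2]
    scale = 1.0 + k1 * r2 + k2 * r2 ** 2
    xd = xn * scale
    proj = sub.pp[front] + sub.foc[front] * xd
    res = proj - pixels[front]
    f = float(np.sum(res ** 2)) + 1e12 * int((~front).sum() > 0) * 0.0

    # chain rule: dproj/dX = diag(foc) @ dxd/dxn @ dxn/dXc @ R
    # dxd_i/dxn_j = scale * delta_ij + xn_i * (k1 + 2 k2 r2) * 2 xn_j
    a = 2.0 * k1 + 4.0 * k2 * r2                       # (n,1)
    J_xd = scale[:, :, None] * np.eye(2) + a[:, :, None] * (xn[:, :, None] @ xn[:, None, :])
    inv_z = 1.0 / z
    J_xn = np.zeros((len(z), 2, 3))
    J_xn[:, 0, 0] = inv_z
    J_xn[:, 1, 1] = inv_z
    J_xn[:, 0, 2] = -xn[:, 0] * inv_z
    J_xn[:, 1, 2] = -xn[:, 1] * inv_z
    J = sub.foc[front][:, :, None] * (J_xd @ J_xn @ Rs)    # (n, 2, 3)
    g = 2.0 * np.einsum("ni,nij->j", res, J)
    # behind-camera views add a fixed penalty so the objective is honest
    n_behind = int((~front).sum())
    if n_behind:
        f += 1e12 * n_behind
    return f, g


def _frame_observations(detections: DetectionSet, names: Sequence[str],
                        cam_index: Mapping[str, int]) -> dict:
    """{(frame, landmark_idx): (camera index array, pixel array)}."""
    obs = {}
    name_to_j = {n: j for j, n in enumerate(names)}
    for (frame, landmark), grp in detections.df.groupby(["frame", "landmark"], sort=True):
        j = name_to_j.get(landmark)
        if j is None:
            continue
        idx = np.array([cam_index[c] for c in grp["camera_id"] if c in cam_index], dtype=int)
        if len(idx):
            obs[(int(frame), j)] = (idx, grp[["x", "y"]].to_numpy(dtype=float))
    return obs


def refine_chain(
    raw: PoseSequence3D,
    detections: DetectionSet,
    cameras: Sequence[CameraModel],
    skeleton: Skeleton,
    limb_lengths: LimbLengths,
    weights: tuple[float, float] = (1.0, 1.0),
    tol: float = 1e-5,
    inlier_threshold_px: float = 10.0,
    hard_length_gate: float | None = None,
    return_diagnostics: bool = False,
):
    """Refine a raw reconstruction along the kinematic chain.

    Landmarks are processed root first, then breadth-first down the tree;
    frames are swept forward so the temporal term anchors to the
    already-refined previous frame (dropped at t=0).  The root is refined
    without the limb term.  Each (landmark, frame) problem is a 3-vector
    minimization solved by BFGS from the raw initialization; if the solver
    fails to improve, the initialization is kept, so the objective is never
    increased.  Invalid raw entries are re-initialized from the refined
    parent plus a rest-length offset along the previous frame's limb
    direction when available.

    ``hard_length_gate`` (off by default) additionally rejects raw
    initializations whose distance to the refined parent violates the
    estimated limb length by more than that fraction (e.g. 0.5 for 50%);
    rejected entries go through the same parent-based re-initialization.
    """
    w_l, w_t = weights
    names = raw.landmark_names
    cam_index = {c.camera_id: i for i, c in enumerate(cameras)}
    stack = _CameraStack(cameras)
    obs = _frame_observations(detections, names, cam_index)

    T, L, _ = raw.positions.shape
    refined = raw.positions.copy()
    valid = raw.valid.copy()
    obj_init = np.full((T, L), np.nan)
    obj_final = np.full((T, L), np.nan)

    order = skeleton.bfs_order()
    name_to_j = {n: j for j, n in enumerate(names)}

    for lm in order:
        j = name_to_j[lm]
        parent = skeleton.parent_of[lm]
        pj = name_to_j[parent] if parent is not None else None
        L_rest = limb_lengths[(parent, lm)] if parent is not None else None

        for t in range(T):
            entry = obs.get((t, j))
            x0 = refined[t, j]
            if valid[t, j] and hard_length_gate is not None and pj is not None \
                    and valid[t, pj]:
                d = np.linalg.norm(x0 - refined[t, pj])
                if abs(d - L_rest) > hard_length_gate * L_rest:
                    valid[t, j] = False    # implausible limb: re-initialize
            if not valid[t, j]:
                # re-initialize from the parent when possible
                if pj is not None and valid[t, pj]:
                    if t > 0 and valid[t - 1, j] and valid[t - 1, pj]:
                        d = refined[t - 1, j] - refined[t - 1, pj]
                        n = np.linalg.norm(d)
                        d = d / n if n > 1e-12 else np.array([0.0, 0.0, 1.0])
                    else:
                        d = np.array([0.0, 0.0, -1.0])
                    x0 = refined[t, pj] + L_rest * d
                    valid[t, j] = True
                else:
                    continue

            cam_idx = entry[0] if entry is not None else np.empty(0, dtype=int)
            pixels = entry[1] if entry is not None else np.empty((0, 2))
            if len(cam_idx):
                # spurious detections (RANSAC outliers) would bias the
                # least-squares term: keep only views consistent with the
                # initialization
                sq0 = stack.subset(cam_idx).sq_reprojection_errors(pixels, x0[None, :])[:, 0]
                keep = sq0 < inlier_threshold_px ** 2
                if keep.any():
                    cam_idx, pixels = cam_idx[keep], pixels[keep]
            sub = stack.subset(cam_idx) if len(cam_idx) else None
            have_parent = pj is not None and valid[t, pj]
            parent_pos = refined[t, pj] if have_parent else None
            have_prev = t > 0 and valid[t - 1, j]
            prev_pos = refined[t - 1, j] if have_prev else None

            def objective(X):
                f, g = 0.0, np.zeros(3)
                if sub is not None:
                    fr, gr = _reprojection_term(sub, pixels, X)
                    f += fr
                    g += gr
                if have_parent:
                    d = X - parent_pos
                    nrm = np.linalg.norm(d)
                    if nrm > 1e-12:
                        f += w_l * (nrm - L_rest) ** 2
                        g += w_l * 2.0 * (nrm - L_rest) * d / nrm
                if have_prev:
                    d = X - prev_pos
                    f += w_t * float(d @ d)
                    g += w_t * 2.0 * d
                return f, g

            f0 = objective(x0)[0]
            obj_init[t, j] = f0
            res = minimize(objective, x0, jac=True, method="BFGS",
                           options={"gtol": tol, "maxiter": 100})
            if np.isfinite(res.fun) and res.fun < f0:
                refined[t, j] = res.x
                obj_final[t, j] = float(res.fun)
            else:
                obj_final[t, j] = f0

    out = PoseSequence3D(refined, valid, names, fps=raw.fps, stage="refined")
    if return_diagnostics:
        return out, RefineDiagnostics(obj_init, obj_final)
    return out
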