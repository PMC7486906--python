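"""Keyframing, crops, view proposal, verification, propagation, augmentation."""

import numpy as np
import pytest

from primatemocap import (
    AnnotationSet,
    InsufficientViewsError,
    MotionScript,
    affine_augment,
    center_of_mass_3d,
    crop_window,
    propagate_labels,
    propose_annotation_views,
    select_keyframes,
    simulate_motion,
    verify_annotations,
)
from primatemocap.annotation_pipeline import DEFAULT_SCALE_CONST
from primatemocap.camera_geometry import project_points


def _exact_annotations(pose, skeleton, cameras, view_ids, frame=0):
    cam = {c.camera_id: c for c in cameras}
    recs = []
    for cid in view_ids:
        for j, name in enumerate(skeleton.landmark_names):
            p, _ = project_points(cam[cid], pose[j])
            recs.append(dict(frame=frame, camera_id=cid, landmark=name,
                             x=float(p[0]), y=float(p[1])))
    return AnnotationSet.from_records(recs)


@pytest.fixture(scope="module")
def sit_pose(skeleton):
    poses, _ = simulate_motion(skeleton, MotionScript.from_pairs([("sit", 0.5)]), seed=1)
    return poses.positions[0]


class TestCenterOfMass:
    def test_noiseless_matches_3d_centroid(self, sit_pose, rig62):
        com = sit_pose.mean(axis=0)
        cents = {}
        for c in rig62:
            pix, depth = project_points(c, sit_pose)
            if np.all(depth > 0):
                cents[c.camera_id] = tuple(pix.mean(axis=0))
        res = center_of_mass_3d(cents, rig62)
        assert res.valid
        assert np.linalg.norm(res.point - com) < 0.05

    def test_single_view_insufficient(self, rig62):
        with pytest.raises(InsufficientViewsError):
            center_of_mass_3d({"cam00": (640.0, 512.0)}, rig62)

    def test_outlier_centroids_rejected(self, sit_pose, rig62):
        rng = np.random.default_rng(4)
        cents, clean = {}, {}
        for i, c in enumerate(rig62):
            pix, _ = project_points(c, sit_pose)
            p = pix.mean(axis=0)
            clean[c.camera_id] = tuple(p)
            if i % 5 == 0:    # 20% gross outliers
                p = np.array([rng.uniform(0, 1279), rng.uniform(0, 1023)])
            cents[c.camera_id] = tuple(p)
        noisy = center_of_mass_3d(cents, rig62)
        ref = center_of_mass_3d(clean, rig62)
        assert np.linalg.norm(noisy.point - ref.point) < 0.05


class TestKeyframes:
    def test_stationary_trajectory_single_keyframe(self):
        com = np.tile([0.1, 0.2, 0.5], (100, 1))
        assert select_keyframes(com, 0.15) == [0]

    def test_zero_threshold_keeps_every_frame(self):
        com = np.tile([0.1, 0.2, 0.5], (10, 1))
        assert select_keyframes(com, 0.0) == list(range(10))

    def test_keyframes_concentrate_in_jump(self, skeleton):
        script = MotionScript.from_pairs([("sit", 10.0), ("jump", 1.0), ("sit", 10.0)])
        poses, _ = simulate_motion(skeleton, script, seed=6)
        kf = select_keyframes(poses.centroid(), 0.15)
        jump_window = range(295, 345)   # jump frames plus the settling ease
        assert kf[0] == 0
        assert all(k in jump_window for k in kf[1:])
        assert len(kf) > 1

    def test_count_monotone_in_threshold(self, skeleton):
        poses, _ = simulate_motion(
            skeleton, MotionScript.from_pairs([("walk", 5.0)]), seed=7)
        com = poses.centroid()
        counts = [len(select_keyframes(com, thr)) for thr in (0.0, 0.05, 0.15, 0.5, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestCropWindow:
    def test_inverse_proportionality(self, rig62):
        cam = rig62[0]
        direction = np.array([0.0, 0.0, 1.375]) - cam.center
        near = cam.center + 0.4 * direction
        far = cam.center + 0.8 * direction
        w_near = crop_window(near, cam)
        w_far = crop_window(far, cam)
        assert np.isclose(w_near.side_px, 2.0 * w_far.side_px, rtol=1e-9)

    def test_anchored_to_150px_at_5p2m(self, rig62):
        # scale_const / 5.2 m ~ 150 px, hence 260 px at 3 m
        assert np.isclose(DEFAULT_SCALE_CONST / 5.2, 150.0, atol=0.1)
        cam = rig62[0]
        p = cam.center + 3.0 * (np.array([0.0, 0.0, 1.375]) - cam.center) \
            / np.linalg.norm(np.array([0.0, 0.0, 1.375]) - cam.center)
        assert np.isclose(crop_window(p, cam).side_px, 260.0, atol=0.5)

    def test_interior_points_fit_inside_image(self, rig62):
        for x in (-0.8, 0.0, 0.8):
            for y in (-0.8, 0.8):
                for z in (0.4, 1.4, 2.2):
                    for cam in rig62[::13]:
                        cw = crop_window(np.array([x, y, z]), cam)
                        assert cw.side_px / 2 <= cw.center_px[0] <= cam.image_size[0] - cw.side_px / 2
                        assert cw.side_px / 2 <= cw.center_px[1] <= cam.image_size[1] - cw.side_px / 2

    def test_crop_coordinate_roundtrip(self, rig62):
        cw = crop_window(np.array([0.2, 0.1, 1.0]), rig62[3])
        pts = np.array([[10.0, 20.0], [350.0, 200.0]])
        np.testing.assert_allclose(cw.image_to_crop(cw.crop_to_image(pts)), pts)


class TestProposeViews:
    def test_square_corners_pick_diagonal(self):
        from primatemocap import CameraModel
        from primatemocap.camera_geometry import look_at_rotation

        corners = [(1.0, 1.0), (1.0, -1.0), (-1.0, -1.0), (-1.0, 1.0)]
        cams = []
        for i, (x, y) in enumerate(corners):
            center = np.array([x, y, 1.0])
            R = look_at_rotation(center, np.zeros(3))
            cams.append(CameraModel(f"c{i}", (500.0, 500.0), (639.5, 511.5),
                                    rotation=R, translation=-R @ center))
        ids = propose_annotation_views(np.array([0.0, 0.0, 0.2]), cams, k=2)
        pair = set(ids)
        assert pair in ({"c0", "c2"}, {"c1", "c3"})

    def test_wide_baselines_on_default_rig(self, rig62):
        ids = propose_annotation_views(np.array([0.0, 0.0, 1.0]), rig62, k=3)
        assert len(ids) == 3
        cam = {c.camera_id: c for c in rig62}
        centers = np.array([cam[i].center for i in ids])
        sel = [np.linalg.norm(centers[i] - centers[j])
               for i in range(3) for j in range(i + 1, 3)]
        allpairs = [np.linalg.norm(a.center - b.center)
                    for i, a in enumerate(rig62) for b in rig62[i + 1:]]
        assert min(sel) >= np.percentile(allpairs, 25)

    def test_k_equal_visible_returns_all(self, rig8):
        ids = propose_annotation_views(np.array([0.0, 0.0, 1.2]), rig8, k=8)
        assert sorted(ids) == sorted(c.camera_id for c in rig8)


class TestVerifyAndPropagate:
    VIEWS = ["cam00", "cam10", "cam20"]

    def test_exact_annotations_unflagged(self, sit_pose, skeleton, rig62):
        ann = _exact_annotations(sit_pose, skeleton, rig62, self.VIEWS)
        report = verify_annotations(ann, rig62)
        assert report.flagged.sum() == 0
        assert np.nanmax(report.error_px) < 1e-6

    def test_single_corrupted_entry_flagged(self, sit_pose, skeleton, rig62):
        ann = _exact_annotations(sit_pose, skeleton, rig62, self.VIEWS)
        df = ann.df.copy()
        df.loc[(df.camera_id == "cam10") & (df.landmark == "left_hand"), "x"] += 50.0
        report = verify_annotations(AnnotationSet(df), rig62, reproj_threshold_px=10.0)
        flagged = report[report.flagged]
        assert [(r.camera_id, r.landmark) for r in flagged.itertuples()] == \
            [("cam10", "left_hand")]

    def test_under_threshold_shift_not_flagged(self, sit_pose, skeleton, rig62):
        # the 10 px gate: smaller errors pass
        ann = _exact_annotations(sit_pose, skeleton, rig62, self.VIEWS)
        df = ann.df.copy()
        df.loc[(df.camera_id == "cam10") & (df.landmark == "left_hand"), "x"] += 4.0
        report = verify_annotations(AnnotationSet(df), rig62, reproj_threshold_px=10.0)
        assert report.flagged.sum() == 0

    def test_two_view_landmark_unverifiable(self, sit_pose, skeleton, rig62):
        ann = _exact_annotations(sit_pose, skeleton, rig62, ["cam00"])
        report = verify_annotations(ann, rig62)
        assert report.unverifiable.all()
        assert report.flagged.sum() == 0

    def test_propagation_matches_ground_truth(self, sit_pose, skeleton, rig62):
        ann = _exact_annotations(sit_pose, skeleton, rig62, self.VIEWS)
        prop = propagate_labels(ann, rig62)
        cam = {c.camera_id: c for c in rig62}
        propagated = prop.df[prop.df.source == "propagated"]
        assert len(propagated) > 0
        for r in propagated.itertuples():
            expect, _ = project_points(cam[r.camera_id],
                                       sit_pose[skeleton.index(r.landmark)])
            assert np.hypot(r.x - expect[0], r.y - expect[1]) < 1e-6

    def test_amplification_factor(self, sit_pose, skeleton, rig62):
        # 3 annotated views propagate to every other visible camera:
        # amplification = visible / annotated, here ~20x
        ann = _exact_annotations(sit_pose, skeleton, rig62, self.VIEWS)
        prop = propagate_labels(ann, rig62)
        per_landmark = prop.df.groupby("landmark").size()
        amp = per_landmark / len(self.VIEWS)
        assert (amp >= 15).all() and (amp <= 62 / 3 + 1e-9).all()

    def test_flagged_view_excluded_from_propagation(self, sit_pose, skeleton, rig62):
        ann = _exact_annotations(sit_pose, skeleton, rig62, ["cam00", "cam10", "cam20", "cam30"])
        df = ann.df.copy()
        df.loc[(df.camera_id == "cam10") & (df.landmark == "nose"), "y"] += 80.0
        prop = propagate_labels(AnnotationSet(df), rig62)
        clean = propagate_labels(ann, rig62)
        a = prop.df[(prop.df.source == "propagated") & (prop.df.landmark == "nose")]
        b = clean.df[(clean.df.source == "propagated") & (clean.df.landmark == "nose")]
        merged = a.merge(b, on=["frame", "camera_id", "landmark"], suffixes=("_p", "_c"))
        assert len(merged) == len(a)
        assert np.hypot(merged.x_p - merged.x_c, merged.y_p - merged.y_c).max() < 1e-6

    def test_propagated_set_self_consistent(self, sit_pose, skeleton, rig62):
        ann = _exact_annotations(sit_pose, skeleton, rig62, self.VIEWS)
        prop = propagate_labels(ann, rig62)
        df = prop.df.copy()
        df["source"] = "human"
        report = verify_annotations(AnnotationSet(df), rig62)
        assert report.flagged.sum() == 0

    def test_propagated_error_bounded_by_annotation_noise(self, sit_pose, skeleton, rig62):
        sigma_a = 2.0
        rng = np.random.default_rng(11)
        ann = _exact_annotations(sit_pose, skeleton, rig62,
                                 ["cam00", "cam08", "cam16", "cam24"])
        df = ann.df.copy()
        df[["x", "y"]] += rng.normal(0, sigma_a, (len(df), 2))
        prop = propagate_labels(AnnotationSet(df), rig62)
        cam = {c.camera_id: c for c in rig62}
        errs = []
        for r in prop.df[prop.df.source == "propagated"].itertuples():
            expect, _ = project_points(cam[r.camera_id],
                                       sit_pose[skeleton.index(r.landmark)])
            errs.append(np.hypot(r.x - expect[0], r.y - expect[1]))
        assert np.max(errs) < 3 * sigma_a


class TestAffineAugment:
    LABELS = {"left_hand": (10.0, 20.0), "right_hand": (100.0, 200.0),
              "nose": (184.0, 184.0)}
    PAIRS = (("left_hand", "right_hand"),)

    def test_exactly_nine_instances(self):
        out = affine_augment(self.LABELS, bilateral_pairs=self.PAIRS)
        assert len(out) == 9
        assert len({o["name"] for o in out}) == 9

    def test_flip_mirrors_and_swaps_sides(self):
        out = {o["name"]: o for o in affine_augment(self.LABELS, bilateral_pairs=self.PAIRS)}
        flip = out["flip"]["labels"]
        assert flip["right_hand"] == (357.0, 20.0)     # mirrored left hand
        assert flip["left_hand"] == (267.0, 200.0)     # mirrored right hand
        assert flip["nose"] == (183.0, 184.0)

    def test_rotation_pair_inverts(self):
        out = {o["name"]: o for o in affine_augment(self.LABELS, bilateral_pairs=self.PAIRS)}
        plus, minus = out["rot+30"]["matrix"], out["rot-30"]["matrix"]
        for pt in self.LABELS.values():
            q = plus[:, :2] @ np.asarray(pt) + plus[:, 2]
            back = minus[:, :2] @ q + minus[:, 2]
            assert np.allclose(back, pt, atol=1e-9)

    def test_out_of_crop_labels_invalid(self):
        labels = {"nose": (360.0, 184.0)}
        out = {o["name"]: o for o in affine_augment(labels)}
        assert out["shift_right"]["labels"]["nose"] is None
        assert out["shift_left"]["labels"]["nose"] is not None
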