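"""Canonical features, clustering, classification, social analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from primatemocap import (
    ACTIONS,
    ActionLabels,
    MotionScript,
    NoiseModel,
    canonicalize,
    canonicalize_sequence,
    classify_actions,
    cooccurrence,
    emulate_detections,
    embed_and_cluster,
    make_rig,
    proxemics,
    simulate_motion,
    track_two_animals,
    transition_matrix,
    vectorize_2d,
)
from primatemocap.core import PoseSequence3D


@pytest.fixture(scope="module")
def walk_pose(skeleton):
    poses, _ = simulate_motion(skeleton, MotionScript.from_pairs([("walk", 0.5)]), seed=2)
    return poses.positions[3]


class TestCanonicalize:
    def test_length_36(self, walk_pose, skeleton):
        assert canonicalize(walk_pose, skeleton).shape == (36,)

    @settings(deadline=None, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        tx=st.floats(-2.0, 2.0),
        ty=st.floats(-2.0, 2.0),
        tz=st.floats(-1.0, 1.0),
        scale=st.floats(0.3, 3.0),
    )
    def test_similarity_invariance(self, walk_pose, skeleton, angle, tx, ty, tz, scale):
        R = np.array([[np.cos(angle), -np.sin(angle), 0.0],
                      [np.sin(angle), np.cos(angle), 0.0],
                      [0.0, 0.0, 1.0]])
        moved = scale * (walk_pose @ R.T) + np.array([tx, ty, tz])
        a = canonicalize(walk_pose, skeleton)
        b = canonicalize(moved, skeleton)
        assert np.abs(a - b).max() < 1e-9

    def test_mirror_equivariance(self, walk_pose, skeleton):
        # reflecting the world and swapping sides mirrors the feature
        M = np.diag([-1.0, 1.0, 1.0])
        mirrored = np.empty_like(walk_pose)
        for j, name in enumerate(skeleton.landmark_names):
            mirrored[j] = M @ walk_pose[skeleton.index(skeleton.mirror_name(name))]
        f = canonicalize(walk_pose, skeleton).reshape(-1, 3)
        fm = canonicalize(mirrored, skeleton).reshape(-1, 3)
        names = [n for n in skeleton.landmark_names if n != "neck"]
        for j, name in enumerate(names):
            src = names.index(skeleton.mirror_name(name))
            assert np.allclose(fm[j], f[src] * np.array([-1.0, 1.0, 1.0]), atol=1e-9)

    def test_hip_lies_on_unit_spine(self, walk_pose, skeleton):
        # spine normalization: the hip feature has unit norm, zero x, and
        # its (y, z) components reproduce the spine-gravity angle
        f = canonicalize(walk_pose, skeleton).reshape(-1, 3)
        names = [n for n in skeleton.landmark_names if n != "neck"]
        hip = f[names.index("hip")]
        assert np.isclose(np.linalg.norm(hip), 1.0, atol=1e-9)
        assert abs(hip[0]) < 1e-9
        spine = walk_pose[skeleton.index("hip")] - walk_pose[skeleton.index("neck")]
        cos_gravity = -spine[2] / np.linalg.norm(spine)   # canonical y is gravity
        assert np.isclose(hip[1], cos_gravity, atol=1e-9)

    def test_zero_spine_raises(self, walk_pose, skeleton):
        bad = walk_pose.copy()
        bad[skeleton.index("hip")] = bad[skeleton.index("neck")]
        with pytest.raises(ValueError):
            canonicalize(bad, skeleton)

    def test_vertical_spine_uses_shoulder_fallback(self, walk_pose, skeleton):
        pose = walk_pose - walk_pose[skeleton.index("neck")]
        pose[skeleton.index("hip")] = np.array([0.0, 0.0, -0.32])
        f = canonicalize(pose, skeleton)
        assert np.all(np.isfinite(f))


class TestVectorize2D:
    def test_length_and_order(self):
        pose = np.arange(26, dtype=float).reshape(13, 2)
        np.testing.assert_array_equal(vectorize_2d(pose), np.arange(26.0))

    def test_zero_pose(self):
        assert not vectorize_2d(np.zeros((13, 2))).any()

    def test_translation_not_removed(self):
        pose = np.random.default_rng(0).uniform(0, 100, (13, 2))
        assert not np.allclose(vectorize_2d(pose), vectorize_2d(pose + 50.0))

    def test_missing_landmark_raises(self):
        pose = np.zeros((13, 2))
        pose[4, 0] = np.nan
        with pytest.raises(ValueError):
            vectorize_2d(pose)


class TestEmbedAndCluster:
    def test_actions_form_recoverable_clusters(self, skeleton):
        rng = np.random.default_rng(42)
        pairs = []
        for _ in range(6):
            for a in rng.permutation(ACTIONS):
                pairs.append((a, 1.0 if a == "jump" else 5.5))
        poses, labels = simulate_motion(skeleton, MotionScript.from_pairs(pairs), seed=11)
        feats, ok = canonicalize_sequence(poses, skeleton)
        emb, cl = embed_and_cluster(feats[ok], seed=3)
        assert emb.shape == (ok.sum(), 2)
        ari = adjusted_rand_score(labels.labels[ok].astype(str), cl.astype(str))
        assert ari >= 0.7
        # partition: every point is clustered or noise-flagged
        assert set(np.unique(cl)) <= set(range(-1, cl.max() + 1))

    def test_duplicated_features_single_cluster(self):
        X = np.tile(np.linspace(0, 1, 36), (80, 1))
        _, cl = embed_and_cluster(X, seed=0)
        assert len(set(cl)) == 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            embed_and_cluster(np.zeros((10, 36)), seed=0)


class TestClassifyActions:
    def test_exact_training_point_k1(self):
        X = np.array([[0.0] * 4, [1.0] * 4, [2.0] * 4])
        y = ["sit", "walk", "jump"]
        pred = classify_actions(X, y, X[[1]], k=1)
        assert pred.labels[0] == "walk"

    def test_single_class_constant_output(self):
        rng = np.random.default_rng(1)
        pred = classify_actions(rng.normal(size=(20, 4)), ["climb"] * 20,
                                rng.normal(size=(7, 4)), k=5)
        assert set(pred.labels) == {"climb"}

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            classify_actions(np.zeros((4, 2)), ["sit"] * 4, np.zeros((1, 2)), k=4)


class TestTransitions:
    def test_constant_labels_single_diagonal(self):
        tm = transition_matrix(ActionLabels(np.array(["sit"] * 10, dtype=object)))
        assert tm[0, 0] == 1.0
        assert tm.sum() == 1.0

    def test_rows_sum_to_one_or_zero(self, skeleton):
        script = MotionScript.from_pairs(
            [("walk", 0.5), ("stand", 0.5), ("climb", 0.5), ("climb_supine", 0.5)])
        _, labels = simulate_motion(skeleton, script, seed=1)
        tm = transition_matrix(labels)
        sums = tm.sum(axis=1)
        assert np.all(np.isclose(sums, 1.0) | np.isclose(sums, 0.0))

    def test_scripted_transitions_only(self, skeleton):
        script = MotionScript.from_pairs(
            [("walk", 0.5), ("stand", 0.5), ("climb", 0.5), ("climb_supine", 0.5)])
        _, labels = simulate_motion(skeleton, script, seed=1)
        tm = transition_matrix(labels)
        idx = {a: i for i, a in enumerate(ACTIONS)}
        expected = {(idx["walk"], idx["walk"]), (idx["walk"], idx["stand"]),
                    (idx["stand"], idx["stand"]), (idx["stand"], idx["climb"]),
                    (idx["climb"], idx["climb"]), (idx["climb"], idx["climb_supine"]),
                    (idx["climb_supine"], idx["climb_supine"])}
        assert set(map(tuple, np.argwhere(tm > 0))) == expected


class TestTwoAnimals:
    @staticmethod
    def _two_animal_detections(skeleton, rig, offset, seeds=(21, 22)):
        pa, _ = simulate_motion(skeleton, MotionScript.from_pairs([("walk", 2.0)]),
                                seed=seeds[0])
        pb, _ = simulate_motion(skeleton, MotionScript.from_pairs([("walk", 2.0)]),
                                seed=seeds[1])
        pos_b = np.clip(pb.positions + np.array(offset), -1.2, None)
        pb = PoseSequence3D(pos_b, pb.valid, pb.landmark_names, stage="ground_truth")
        da = emulate_detections(pa, rig, NoiseModel(pixel_sigma=1.0, seed=31)).df.assign(instance=0)
        db = emulate_detections(pb, rig, NoiseModel(pixel_sigma=1.0, seed=32)).df.assign(instance=1)
        det = pd.concat([da, db], ignore_index=True)
        rng = np.random.default_rng(0)
        for cam in det.camera_id.unique():   # instance ids arbitrary per camera
            if rng.random() < 0.5:
                m = det.camera_id == cam
                det.loc[m, "instance"] = 1 - det.loc[m, "instance"]
        return pa, pb, det

    def test_crossing_paths_zero_identity_swaps(self, skeleton, rig62):
        pa, pb, det = self._two_animal_detections(skeleton, rig62, (0.6, 0.6, 0.0))
        ra, rb, diag = track_two_animals(det, rig62, list(skeleton.landmark_names), seed=5)
        nj = skeleton.index("neck")
        m = ra.valid[:, nj] & rb.valid[:, nj]
        assert m.sum() > 20
        direct = (np.linalg.norm(ra.positions[m, nj] - pa.positions[m, nj], axis=1).mean()
                  + np.linalg.norm(rb.positions[m, nj] - pb.positions[m, nj], axis=1).mean())
        swapped = (np.linalg.norm(ra.positions[m, nj] - pb.positions[m, nj], axis=1).mean()
                   + np.linalg.norm(rb.positions[m, nj] - pa.positions[m, nj], axis=1).mean())
        best = min(direct, swapped)
        assert best < 0.05   # one consistent identity for the whole sequence
        ref_a, ref_b = (pa, pb) if direct < swapped else (pb, pa)
        assert np.linalg.norm(ra.positions[m, nj] - ref_a.positions[m, nj], axis=1).max() < 0.05
        assert np.linalg.norm(rb.positions[m, nj] - ref_b.positions[m, nj], axis=1).max() < 0.05

    def test_single_animal_degenerate_split_flagged(self, skeleton, rig62):
        poses, _ = simulate_motion(skeleton, MotionScript.from_pairs([("sit", 1.0)]), seed=9)
        det = emulate_detections(poses, rig62, NoiseModel(pixel_sigma=1.0, seed=2)).df.assign(instance=0)
        _, _, diag = track_two_animals(det, rig62, list(skeleton.landmark_names), seed=5)
        flagged = set(diag.degenerate_frames) | set(diag.ambiguous_frames)
        assert len(flagged) == poses.n_frames


class TestCooccurrence:
    def test_identical_streams_diagonal(self):
        labels = np.array(["sit", "walk", "sit", "jump"], dtype=object)
        co = cooccurrence(labels, labels)
        assert co.sum() == 4
        assert np.all(co == np.diag(np.diag(co)))

    def test_total_count_conserved_and_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        a = rng.choice(ACTIONS, 100)
        b = rng.choice(ACTIONS, 100)
        assert cooccurrence(a, b).sum() == 100
        with pytest.raises(ValueError):
            cooccurrence(a, b[:-1])

    def test_independent_uniform_streams(self):
        rng = np.random.default_rng(4)
        n = 10_000
        a = rng.choice(ACTIONS, n)
        b = rng.choice(ACTIONS, n)
        co = cooccurrence(a, b)
        expect = n / 36
        se = np.sqrt(n * (1 / 36) * (1 - 1 / 36))
        assert np.abs(co - expect).max() < 3 * se


class TestProxemics:
    @staticmethod
    def _static_pair(skeleton, offset, n=50):
        poses, _ = simulate_motion(skeleton, MotionScript.from_pairs([("stand", n / 30.0)]),
                                   seed=13)
        a = poses
        b = PoseSequence3D(poses.positions + np.asarray(offset), poses.valid,
                           poses.landmark_names)
        return a, b

    def test_conspecific_dead_ahead(self, skeleton):
        from primatemocap import facing_direction

        a, _ = self._static_pair(skeleton, (0, 0, 0))
        # place B exactly 1 m along A's facing direction every frame
        pos_b = a.positions.copy()
        for t in range(a.n_frames):
            f = facing_direction(a.positions[t], skeleton)
            pos_b[t] += f * 1.0
        b = PoseSequence3D(pos_b, a.valid, a.landmark_names)
        h = proxemics(a, b, skeleton,
                      r_edges=np.array([0.0, 0.9, 1.1, 3.0]),
                      theta_edges=np.array([-180.0, -15.0, 15.0, 180.0]))
        assert np.isclose(h.mass.sum(), 1.0)
        assert np.isclose(h.mass[1, 1], 1.0)

    def test_uniform_ring_flat_theta_marginal(self, skeleton):
        a, _ = self._static_pair(skeleton, (0, 0, 0), n=240)
        rng = np.random.default_rng(17)
        pos_b = a.positions.copy()
        thetas = rng.uniform(-np.pi, np.pi, a.n_frames)
        for t in range(a.n_frames):
            pos_b[t] += np.array([np.cos(thetas[t]), np.sin(thetas[t]), 0.0])
        b = PoseSequence3D(pos_b, a.valid, a.landmark_names)
        h = proxemics(a, b, skeleton,
                      theta_edges=np.linspace(-180, 180, 5))
        marginal = h.mass.sum(axis=0)
        n = h.n_frames
        se = np.sqrt(n * 0.25 * 0.75) / n
        assert np.abs(marginal - 0.25).max() < 3 * se

    def test_invalid_necks_skipped_and_counted(self, skeleton):
        a, b = self._static_pair(skeleton, (1.0, 0, 0))
        valid = a.valid.copy()
        valid[:10, skeleton.index("neck")] = False
        a_broken = PoseSequence3D(a.positions, valid, a.landmark_names)
        h = proxemics(a_broken, b, skeleton)
        assert h.n_skipped == 10
        assert np.isclose(h.mass.sum(), 1.0)
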