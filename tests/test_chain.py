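"""Local frames, joint-center estimation, and the decompose/reconstruct
round trip, checked against the generator's exact forward model."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from bowfreeze import simulate as sim
from bowfreeze.chain import (
    DegeneracyError,
    RigidMotionSeries,
    build_segment_frames,
    chain_to_table,
    decompose,
    estimate_joint_centers,
    gram_schmidt_frame,
    load_chain_table,
    reconstruct,
    rotation_angles,
    save_chain,
)
from bowfreeze.simulate import preset, simulate_trial


def transformed(trial, rot: np.ndarray, shift: np.ndarray):
    out = trial.copy()
    out.positions = np.einsum("ij,nmj->nmi", rot, out.positions) + shift
    return out


class TestGramSchmidt:
    def test_canonical_basis_is_identity(self):
        basis = gram_schmidt_frame(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        assert np.allclose(basis, np.eye(3), atol=1e-12)

    def test_collinear_raises(self):
        with pytest.raises(DegeneracyError):
            gram_schmidt_frame(np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))

    def test_oblique_pair(self):
        basis = gram_schmidt_frame(np.array([1.0, 1.0, 0]), np.array([0, 3.0, 0]))
        assert np.allclose(basis.T @ basis, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(basis), 1.0, atol=1e-12)
        assert np.allclose(basis[:, 0], np.array([1, 1, 0]) / np.sqrt(2))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_pairs_orthonormal_right_handed(self, seed):
        rng = np.random.default_rng(seed)
        p, s = rng.normal(size=3), rng.normal(size=3)
        cross = np.linalg.norm(np.cross(p, s))
        if cross < 1e-3 * np.linalg.norm(p) * np.linalg.norm(s):
            return
        basis = gram_schmidt_frame(p, s)
        assert np.allclose(basis.T @ basis, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(basis), 1.0, atol=1e-9)
        assert np.allclose(basis[:, 0], p / np.linalg.norm(p), atol=1e-9)


class TestJointCenters:
    def test_zero_override_keeps_marker(self, tiny_trial):
        out = estimate_joint_centers(tiny_trial, elbow_width_mm=0.0)
        assert np.allclose(out.marker("elbow_jc"), out.marker("elbow_lateral"))

    def test_double_call_rejected(self, tiny_trial):
        out = estimate_joint_centers(tiny_trial)
        with pytest.raises(ValueError, match="already present"):
            estimate_joint_centers(out)

    def test_negative_width_rejected(self, tiny_trial):
        with pytest.raises(ValueError):
            estimate_joint_centers(tiny_trial, wrist_width_mm=-1.0)

    def test_simulator_centers_recovered_exactly(self, novice_clean):
        """The fixed-point marker placement makes the anthropometric offsets
        land on the generator's true joint centers."""
        trial, truth = novice_clean
        out = estimate_joint_centers(trial)
        a1 = sim.ALPHA1_MEAN + truth.elevation["shoulder"]
        a2 = a1 + sim.BETA2_MEAN + truth.elevation["elbow"]
        elbow_true = sim.SHOULDER + sim.L_UPPER * np.stack(
            [np.cos(a1), np.zeros_like(a1), np.sin(a1)], axis=-1
        )
        wrist_true = elbow_true + sim.L_LOWER * np.stack(
            [np.cos(a2), np.zeros_like(a2), np.sin(a2)], axis=-1
        )
        assert np.abs(out.marker("elbow_jc") - elbow_true).max() < 1e-8
        assert np.abs(out.marker("wrist_jc") - wrist_true).max() < 1e-8
        assert np.allclose(out.marker("shoulder_jc"), out.marker("acromion"))


class TestSegmentFrames:
    def test_all_bases_orthonormal_on_simulated_trial(self, expert_noisy):
        trial, _ = expert_noisy
        frames, valid = build_segment_frames(estimate_joint_centers(trial))
        assert valid.all()
        for name, series in frames.items():
            prod = np.einsum("nji,njk->nik", series.rot, series.rot)
            assert np.abs(prod - np.eye(3)).max() < 1e-9, name
            assert np.allclose(np.linalg.det(series.rot), 1.0, atol=1e-9), name

    def test_extended_elbow_flagged_degenerate(self, tiny_trial):
        """Collinear shoulder-elbow-wrist makes the upper-arm frame
        degenerate; those frames are flagged, not patched."""
        trial = estimate_joint_centers(tiny_trial, elbow_width_mm=0.0,
                                       wrist_width_mm=0.0)
        jc = trial.index_of("elbow_jc")
        sh = trial.index_of("shoulder_jc")
        wr = trial.index_of("wrist_jc")
        trial.positions[:, jc] = 0.5 * (trial.positions[:, sh] + trial.positions[:, wr])
        _, valid = build_segment_frames(trial)
        assert not valid.any()


class TestRoundTrip:
    def test_reconstruct_inverts_decompose(self, expert_noisy):
        trial, _ = expert_noisy
        tv = estimate_joint_centers(trial)
        rec = reconstruct(decompose(tv))
        assert tv.n_frames > 1000
        assert np.nanmax(np.abs(rec.positions - tv.positions)) < 1e-6
        assert np.array_equal(rec.missing, tv.missing)

    def test_static_trial_constant_joints(self, static_trial):
        chain = decompose(estimate_joint_centers(static_trial))
        for name, joint in chain.joints.items():
            assert rotation_angles(joint).max() < 1e-9, name
            assert np.ptp(joint.trans, axis=0).max() < 1e-9, name

    def test_programmed_angles_recovered(self, novice_clean):
        trial, truth = novice_clean
        chain = decompose(estimate_joint_centers(trial))
        got = rotation_angles(chain.joints["shoulder"])
        want = np.abs(truth.elevation["shoulder"] - truth.elevation["shoulder"][0])
        assert np.abs(got - want).max() < 1e-6
        assert rotation_angles(chain.joints["elbow"]).max() < 1e-6
        assert rotation_angles(chain.joints["wrist"]).max() < 1e-6

    def test_shoulder_only_motion_keeps_bow_radius(self, novice_clean):
        """With one rotating joint the bow markers ride circles about the
        shoulder: their distance to the joint center is constant."""
        trial, _ = novice_clean
        radius = np.linalg.norm(trial.marker("bow_tip") - trial.marker("acromion"), axis=1)
        assert np.ptp(radius) < 1e-6


class TestEquivariance:
    def test_vertical_preserving_transform_moves_root_only(self, expert_noisy):
        trial, _ = expert_noisy
        rot = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        shift = np.array([250.0, -130.0, 75.0])
        a = decompose(estimate_joint_centers(trial))
        b = decompose(estimate_joint_centers(transformed(trial, rot, shift)))
        for name in ("shoulder", "elbow", "wrist", "hand_to_bow"):
            assert np.abs(a.joints[name].rot - b.joints[name].rot).max() < 1e-9
            assert np.abs(a.joints[name].trans - b.joints[name].trans).max() < 1e-9
        assert np.abs(a.root_pose.trans - b.root_pose.trans).max() > 1.0

    def test_arbitrary_rotation_leaves_distal_joints_invariant(self, expert_noisy):
        """The trunk frame uses the lab vertical, so only joints distal to it
        are equivariant under arbitrary rotations."""
        trial, _ = expert_noisy
        rot = Rotation.from_euler("xyz", [20.0, -35.0, 60.0], degrees=True).as_matrix()
        a = decompose(estimate_joint_centers(trial))
        b = decompose(estimate_joint_centers(transformed(trial, rot, np.zeros(3))))
        for name in ("elbow", "wrist", "hand_to_bow"):
            assert np.abs(a.joints[name].rot - b.joints[name].rot).max() < 1e-9
            assert np.abs(a.joints[name].trans - b.joints[name].trans).max() < 1e-9


class TestComposition:
    def test_long_composition_chain_stays_orthonormal(self):
        rng = np.random.default_rng(3)
        acc = RigidMotionSeries.identity(1)
        for _ in range(150):
            step = RigidMotionSeries(
                Rotation.random(1, rng=rng).as_matrix(), rng.normal(size=(1, 3))
            )
            acc = acc.compose(step)
        drift = np.abs(acc.rot[0].T @ acc.rot[0] - np.eye(3)).max()
        assert drift < 1e-9

    def test_inverse_cancels(self):
        rng = np.random.default_rng(4)
        m = RigidMotionSeries(Rotation.random(5, rng=rng).as_matrix(), rng.normal(size=(5, 3)))
        ident = m.compose(m.inverse())
        assert np.abs(ident.rot - np.eye(3)).max() < 1e-12
        assert np.abs(ident.trans).max() < 1e-9


class TestChainExport:
    def test_pose_table_round_trip(self, tmp_path, novice_clean):
        trial, _ = novice_clean
        chain = decompose(estimate_joint_centers(trial))
        path = tmp_path / "chain.tsv"
        save_chain(chain, path)
        back = load_chain_table(path)
        assert np.abs(back["shoulder"].rot - chain.joints["shoulder"].rot).max() < 1e-8
        assert np.abs(back["root"].trans - chain.root_pose.trans).max() < 1e-6
        table = chain_to_table(chain)
        assert len(table) == chain.n_frames
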