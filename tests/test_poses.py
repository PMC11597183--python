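"""Tests for pose RMSD and redocking pose selection."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from snplie import LigandPose, pose_rmsd, read_pose_csv, read_poses_pdb, select_best_poses
from snplie.synth import gen_jittered_poses


def shifted(pose, delta):
    return LigandPose(pose.ligand, pose.atom_names, pose.coords + np.asarray(delta))


class TestPoseRmsd:
    def test_identical_poses_zero(self, reference_pose):
        assert pose_rmsd(reference_pose, reference_pose) == 0.0

    def test_uniform_translation(self, reference_pose):
        assert pose_rmsd(reference_pose, shifted(reference_pose, (3.0, 0.0, 0.0))) == pytest.approx(3.0)

    def test_rigid_motion_vanishes_under_alignment(self, reference_pose):
        rot = Rotation.from_euler("zyx", [40, -25, 100], degrees=True)
        moved = LigandPose(
            reference_pose.ligand,
            reference_pose.atom_names,
            rot.apply(reference_pose.coords) + np.array([5.0, -2.0, 1.0]),
        )
        assert pose_rmsd(reference_pose, moved, align=True) <= 1e-6
        assert pose_rmsd(reference_pose, moved, align=False) > 1.0

    def test_gaussian_jitter_matches_chi_expectation(self):
        rng = np.random.default_rng(8)
        big = LigandPose("lig", [f"C{i}" for i in range(1000)],
                         rng.normal(scale=4.0, size=(1000, 3)))
        sigma = 1.0
        for pose in gen_jittered_poses(big, sigma, 3, seed=9):
            assert pose_rmsd(big, pose) == pytest.approx(sigma * math.sqrt(3), rel=0.05)

    def test_alignment_never_increases_rmsd(self, reference_pose):
        rng = np.random.default_rng(10)
        for _ in range(10):
            other = LigandPose(
                reference_pose.ligand, reference_pose.atom_names,
                reference_pose.coords + rng.normal(scale=2.0, size=reference_pose.coords.shape),
            )
            assert pose_rmsd(reference_pose, other, align=True) <= pose_rmsd(
                reference_pose, other, align=False
            ) + 1e-12

    def test_pseudometric_properties(self, reference_pose):
        rng = np.random.default_rng(11)
        a = reference_pose
        b = shifted(a, rng.normal(size=3))
        c = LigandPose(a.ligand, a.atom_names, a.coords + rng.normal(scale=1.5, size=a.coords.shape))
        assert pose_rmsd(a, b) == pytest.approx(pose_rmsd(b, a))
        assert pose_rmsd(a, c) <= pose_rmsd(a, b) + pose_rmsd(b, c) + 1e-12

    def test_atom_name_mismatch_names_first_offender(self, reference_pose):
        other = LigandPose(reference_pose.ligand,
                           ("X0",) + reference_pose.atom_names[1:],
                           reference_pose.coords)
        with pytest.raises(ValueError, match="index 0"):
            pose_rmsd(reference_pose, other)

    def test_length_mismatch_rejected(self, reference_pose):
        other = LigandPose("lig", reference_pose.atom_names[:-1],
                           reference_pose.coords[:-1])
        with pytest.raises(ValueError, match="atom counts"):
            pose_rmsd(reference_pose, other)


class TestSelectBestPoses:
    def planted_fixture(self, reference_pose):
        """100 candidates; exactly 3 of the 10 best-scoring are small
        perturbations of the native pose."""
        rng = np.random.default_rng(12)
        near_sigmas = [0.02, 0.05, 0.10]
        poses = []
        for k, sig in enumerate(near_sigmas):  # planted near-natives, best scores
            coords = reference_pose.coords + rng.normal(scale=sig, size=reference_pose.coords.shape)
            poses.append(LigandPose("testlig", reference_pose.atom_names, coords, score=1.0 + 0.1 * k))
        for k in range(7):  # well-scoring decoys, far from native
            coords = reference_pose.coords + np.array([6.0 + k, 2.0, -3.0])
            poses.append(LigandPose("testlig", reference_pose.atom_names, coords, score=2.0 + 0.1 * k))
        for k in range(90):  # near-native but poorly scoring: outside top_n
            coords = reference_pose.coords + rng.normal(scale=0.01, size=reference_pose.coords.shape)
            poses.append(LigandPose("testlig", reference_pose.atom_names, coords, score=10.0 + k))
        return poses, near_sigmas

    def test_planted_near_natives_recovered_in_jitter_order(self, reference_pose):
        poses, near_sigmas = self.planted_fixture(reference_pose)
        selection = select_best_poses(poses, reference_pose, top_n=10, keep_k=3)
        scores = [p.score for p, _ in selection]
        assert scores == [1.0, 1.1, 1.2]  # ascending jitter magnitude order
        rmsds = [r for _, r in selection]
        assert rmsds == sorted(rmsds)
        assert all(r < 0.5 for r in rmsds)

    def test_reference_itself_is_a_perfect_pose(self, reference_pose):
        only = LigandPose(reference_pose.ligand, reference_pose.atom_names,
                          reference_pose.coords, score=-5.0)
        selection = select_best_poses([only], only, top_n=1, keep_k=1)
        assert selection[0][1] == 0.0

    def test_too_few_poses_raises(self, reference_pose):
        only = LigandPose(reference_pose.ligand, reference_pose.atom_names,
                          reference_pose.coords, score=0.0)
        with pytest.raises(ValueError, match="at least"):
            select_best_poses([only], only, top_n=3, keep_k=3)

    def test_unscored_pose_rejected(self, reference_pose):
        with pytest.raises(ValueError, match="score"):
            select_best_poses([reference_pose], reference_pose, top_n=1, keep_k=1)


class TestPoseReaders:
    def test_csv_roundtrip_drops_hydrogens(self, tmp_path):
        p = tmp_path / "pose.csv"
        p.write_text(
            "atom_name,x,y,z\nC1,0.0,0.0,0.0\nH1,9.0,9.0,9.0\nN1,1.0,1.0,1.0\n"
        )
        pose = read_pose_csv(p, ligand="lig")
        assert pose.atom_names == ("C1", "N1")
        all_atoms = read_pose_csv(p, ligand="lig", drop_hydrogens=False)
        assert all_atoms.n_atoms == 3

    def test_pdb_multi_model_hetatm(self, tmp_path):
        lines = []
        for model in (1, 2):
            lines.append(f"MODEL     {model:>4}")
            for i, (x, y, z) in enumerate([(0.0, 0.0, 0.0), (1.5, 0.0, 0.0)], start=1):
                shift = 0.0 if model == 1 else 3.0
                lines.append(
                    f"HETATM{i:>5}  C{i}  LIG A 401    "
                    f"{x + shift:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        p = tmp_path / "poses.pdb"
        p.write_text("\n".join(lines) + "\n")
        poses = read_poses_pdb(p, residue_name="LIG")
        assert len(poses) == 2
        assert pose_rmsd(poses[0], poses[1]) == pytest.approx(3.0)

    def test_pdb_missing_residue_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(Exception):
            read_poses_pdb(p, residue_name="LIG")
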