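"""Pairwise-RMSD matrices and neighbour-count clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import thermoseg as ts
from thermoseg.errors import ChainLookupError, ValidationError


def _toy_trajectory(n_frames=6, seed=0):
    sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=25, seed=seed))
    base = sa.coords()
    rng = np.random.default_rng(seed)
    frames = np.stack([base + rng.normal(scale=0.05, size=base.shape)
                       for _ in range(n_frames)])
    return ts.Trajectory(sa, frames, 10.0)


class TestPairwiseRmsdMatrix:
    def test_duplicate_frames_all_zero(self):
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=20, seed=1))
        frames = np.stack([sa.coords()] * 4)
        mat, _ = ts.pairwise_rmsd_matrix(ts.Trajectory(sa, frames, 1.0))
        assert np.abs(mat).max() < 1e-12

    def test_rigidly_rotated_frame_zero_entry(self):
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=20, seed=2))
        base = sa.coords()
        rot = base @ Rotation.random(random_state=3).as_matrix().T + 1.0
        frames = np.stack([base, base, rot])
        mat, _ = ts.pairwise_rmsd_matrix(ts.Trajectory(sa, frames, 1.0))
        assert mat[1, 2] < 1e-9

    def test_matches_direct_reference_loop(self):
        traj = _toy_trajectory(n_frames=6, seed=4)
        mat, frames = ts.pairwise_rmsd_matrix(traj)
        sel = [i for i, (_r, a) in enumerate(traj.topology.atoms())
               if not a.is_hydrogen]
        for i in range(6):
            for j in range(6):
                A = traj.frames[i][sel]
                B = traj.frames[j][sel]
                rot, _ = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
                ref = np.sqrt((((B - B.mean(0)) @ rot.as_matrix().T
                                - (A - A.mean(0))) ** 2).sum() / len(sel))
                assert mat[i, j] == pytest.approx(ref, abs=1e-10)
        assert np.abs(mat - mat.T).max() < 1e-12

    def test_stride_reduces_frames(self):
        traj = _toy_trajectory(n_frames=10)
        mat, frames = ts.pairwise_rmsd_matrix(traj, stride=2)
        assert mat.shape == (5, 5)
        assert list(frames) == [0, 2, 4, 6, 8]


class TestDauraCluster:
    def test_single_frame_is_its_own_center(self):
        res = ts.daura_cluster(np.zeros((1, 1)), cutoff=0.1)
        assert res.n_clusters == 1 and res.centers[0] == 0

    def test_two_groups_hand_constructed(self):
        # frames 0-3 tight, frames 4-5 tight, groups far apart
        n = 6
        mat = np.full((n, n), 1.0)
        np.fill_diagonal(mat, 0.0)
        for grp in ([0, 1, 2, 3], [4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        mat[i, j] = 0.05
        res = ts.daura_cluster(mat, cutoff=0.1)
        assert res.n_clusters == 2
        assert res.sizes == {0: 4, 1: 2}
        assert res.centers == {0: 0, 1: 4}  # lowest index on neighbour ties
        assert [res.assignments[i] for i in range(6)] == [0, 0, 0, 0, 1, 1]

    def test_cutoff_above_max_single_cluster(self):
        traj = _toy_trajectory()
        mat, _ = ts.pairwise_rmsd_matrix(traj)
        res = ts.daura_cluster(mat, cutoff=mat.max() + 1.0)
        assert res.n_clusters == 1
        assert res.sizes[0] == mat.shape[0]

    def test_tiny_cutoff_every_frame_alone(self):
        traj = _toy_trajectory()
        mat, _ = ts.pairwise_rmsd_matrix(traj)
        res = ts.daura_cluster(mat, cutoff=1e-12)
        assert res.n_clusters == mat.shape[0]

    def test_cluster_count_non_increasing_in_cutoff(self):
        # asserted on separated-group geometry; the greedy scheme can strand
        # singletons on unstructured matrices, so monotonicity is a property
        # of resolvable conformational basins, not of arbitrary inputs
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = rng.normal(scale=50.0, size=(4, 3))
            pts = np.concatenate(
                [c + rng.normal(scale=0.5, size=(5, 3)) for c in centers])
            mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            counts = [ts.daura_cluster(mat, c).n_clusters
                      for c in np.geomspace(0.1, 300.0, 15)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_permutation_yields_same_clusters_relabelled(self):
        traj = _toy_trajectory(n_frames=8, seed=9)
        mat, _ = ts.pairwise_rmsd_matrix(traj)
        res = ts.daura_cluster(mat, cutoff=np.median(mat))
        perm = np.random.default_rng(1).permutation(8)
        res_p = ts.daura_cluster(mat[np.ix_(perm, perm)], cutoff=np.median(mat))
        # partition must map through the permutation
        groups = {}
        for new_i, old_i in enumerate(perm):
            groups.setdefault(res_p.assignments[new_i], set()).add(old_i)
        original = {}
        for frame, cid in res.assignments.items():
            original.setdefault(cid, set()).add(frame)
        assert sorted(map(sorted, groups.values())) == \
            sorted(map(sorted, original.values()))

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            ts.daura_cluster(mat, 0.5)


class TestRepresentativeStructure:
    def test_one_frame_trajectory(self):
        traj = _toy_trajectory(n_frames=2)
        mat, frames = ts.pairwise_rmsd_matrix(traj)
        res = ts.daura_cluster(mat, cutoff=10.0)
        rep = ts.representative_structure(traj, res, 0, frames)
        assert np.allclose(rep.coords(), traj.frames[res.centers[0]])

    def test_round_trip_preserves_center_coords(self, tmp_path):
        traj = _toy_trajectory(n_frames=6, seed=12)
        mat, frames = ts.pairwise_rmsd_matrix(traj)
        res = ts.daura_cluster(mat, cutoff=float(np.median(mat)))
        rep = ts.representative_structure(traj, res, 0, frames)
        path = tmp_path / "center.pdb"
        ts.write_pdb(rep, str(path))
        back = ts.read_pdb(str(path))
        assert np.abs(back.coords() - rep.coords()).max() < 1e-4

    def test_unknown_cluster_id(self):
        traj = _toy_trajectory()
        mat, frames = ts.pairwise_rmsd_matrix(traj)
        res = ts.daura_cluster(mat, cutoff=1.0)
        with pytest.raises(ChainLookupError):
            ts.representative_structure(traj, res, 99, frames)
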