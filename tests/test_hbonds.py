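"""Hydrogen-bond detection, occupancy aggregation, block errors, RMSD."""

import numpy as np
import pytest

import thermoseg as ts
from thermoseg.errors import InsufficientDataError, ValidationError
from thermoseg.hbonds import make_pair_key

from conftest import brute_force_hbonds, make_donor_acceptor_frame


def _detect(structure, criteria=None):
    damap = ts.assign_donors_acceptors(structure, hydrogens_present=True)
    return ts.detect_frame_hbonds(structure, structure.coords(), damap,
                                  criteria or ts.HBondCriteria())


class TestDetection:
    def test_both_criteria_met(self):
        s = make_donor_acceptor_frame(da_dist=0.30, hda_angle_deg=10.0)
        events = _detect(s)
        assert len(events) == 1
        assert events[0].donor == (("A", 1), "N")
        assert events[0].acceptor == (("A", 5), "O")

    @pytest.mark.parametrize("dist,angle", [(0.36, 0.0), (0.30, 31.0)])
    def test_single_criterion_failures(self, dist, angle):
        s = make_donor_acceptor_frame(da_dist=dist, hda_angle_deg=angle)
        assert _detect(s) == []

    def test_boundary_values_count(self):
        # criteria are inclusive: <= 0.35 nm and <= 30 degrees
        s = make_donor_acceptor_frame(da_dist=0.35, hda_angle_deg=30.0)
        assert len(_detect(s)) == 1

    def test_matches_brute_force_on_random_frames(self):
        crit = ts.HBondCriteria()
        for seed in range(25):
            rng = np.random.default_rng(seed)
            spec = ts.TrajectorySpec(
                variant="v", temperature="t", n_frames=1,
                pair_schedule=[ts.PairSchedule(1, 2, 1.0),
                               ts.PairSchedule(3, 4, 1.0, 2.0),
                               ts.PairSchedule(5, 6, 0.0)],
                seed=seed)
            traj, _ = ts.make_hbond_trajectory(spec)
            # jitter everything so near-threshold geometry is exercised
            coords = traj.frames[0] + rng.normal(scale=0.08, size=traj.frames[0].shape)
            damap = ts.assign_donors_acceptors(traj.topology, hydrogens_present=True)
            got = {(e.donor, e.hydrogen, e.acceptor)
                   for e in ts.detect_frame_hbonds(traj.topology, coords, damap, crit)}
            ref = brute_force_hbonds(traj.topology, coords, damap, crit)
            assert got == ref

    def test_event_set_monotone_in_criteria(self):
        loose = ts.HBondCriteria(max_da_dist=0.45, max_hda_angle=45)
        tight = ts.HBondCriteria(max_da_dist=0.35, max_hda_angle=30)
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=1,
                                     pair_schedule=[ts.PairSchedule(1, 2, 1.0)],
                                     seed=seed)
            traj, _ = ts.make_hbond_trajectory(spec)
            coords = traj.frames[0] + rng.normal(scale=0.1, size=traj.frames[0].shape)
            damap = ts.assign_donors_acceptors(traj.topology, hydrogens_present=True)
            ev_tight = {(e.donor, e.hydrogen, e.acceptor) for e in
                        ts.detect_frame_hbonds(traj.topology, coords, damap, tight)}
            ev_loose = {(e.donor, e.hydrogen, e.acceptor) for e in
                        ts.detect_frame_hbonds(traj.topology, coords, damap, loose)}
            assert ev_tight <= ev_loose


class TestOccupancyStats:
    def _stats(self, spec):
        traj, truth = ts.make_hbond_trajectory(spec)
        damap = ts.assign_donors_acceptors(traj.topology, hydrogens_present=True)
        return ts.pair_occupancy_stats(traj, damap), truth, traj

    def test_always_bonded_pair_full_occupancy(self):
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=100,
                                 pair_schedule=[ts.PairSchedule(1, 5, 1.0)], seed=0)
        stats, _, _ = self._stats(spec)
        key = make_pair_key(("A", 1), ("A", 5))
        assert stats[key].occupancy == 1.0

    def test_prescribed_occupancy_is_exact(self):
        # 74% of 2000 frames, mirroring a stress-temperature contact
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=2000,
                                 pair_schedule=[ts.PairSchedule(42, 405, 0.74)],
                                 seed=3)
        stats, _, _ = self._stats(spec)
        key = make_pair_key(("A", 42), ("A", 405))
        assert stats[key].occupancy == pytest.approx(0.74, abs=0)

    def test_two_bonds_half_frames(self):
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=100,
                                 pair_schedule=[ts.PairSchedule(1, 5, 0.5, 1.0)],
                                 seed=1)
        stats, _, _ = self._stats(spec)
        rec = stats[make_pair_key(("A", 1), ("A", 5))]
        assert rec.occupancy == 0.5
        assert rec.mean_count == 1.0

    def test_mean_count_at_least_occupancy(self):
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=200,
                                 pair_schedule=[ts.PairSchedule(1, 5, 0.4, 0.7),
                                                ts.PairSchedule(2, 6, 0.9)],
                                 seed=2)
        stats, _, _ = self._stats(spec)
        for rec in stats.values():
            assert rec.mean_count >= rec.occupancy

    def test_invariant_under_frame_permutation(self):
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=300,
                                 pair_schedule=[ts.PairSchedule(1, 5, 0.33, 0.5)],
                                 seed=5)
        traj, _ = ts.make_hbond_trajectory(spec)
        damap = ts.assign_donors_acceptors(traj.topology, hydrogens_present=True)
        base = ts.pair_occupancy_stats(traj, damap)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = ts.Trajectory(traj.topology, traj.frames[perm], traj.frame_spacing)
        other = ts.pair_occupancy_stats(shuffled, damap)
        key = make_pair_key(("A", 1), ("A", 5))
        assert other[key].occupancy == base[key].occupancy
        assert other[key].mean_count == base[key].mean_count

    def test_missing_pair_lookup_error(self):
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=10,
                                 pair_schedule=[ts.PairSchedule(1, 5, 1.0)], seed=0)
        traj, _ = ts.make_hbond_trajectory(spec)
        damap = ts.assign_donors_acceptors(traj.topology, hydrogens_present=True)
        from thermoseg.errors import ChainLookupError
        with pytest.raises(ChainLookupError):
            ts.pair_occupancy_stats(traj, damap,
                                    pairs=[(("A", 1), ("A", 999))])


class TestBlockStandardError:
    def test_constant_series_zero(self):
        assert ts.block_standard_error([2.0] * 100, 10.0, 1.0) == 0.0

    def test_closed_form_five_blocks(self):
        # block means 1..5 -> sd = sqrt(2.5), se = sd/sqrt(5) = 0.7071
        series = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 10)
        se = ts.block_standard_error(series, block_duration=10.0, frame_spacing=1.0)
        assert se == pytest.approx(np.sqrt(2.5) / np.sqrt(5), abs=1e-12)
        assert se == pytest.approx(0.7071, abs=1e-4)

    def test_fifty_ns_at_one_ps_gives_five_blocks(self):
        # 50,000 frames at 1 ps spacing with 10 ns blocks -> exactly 5 blocks
        series = np.zeros(50_000)
        series[:10_000] = 1.0  # one block differs, so se is computable and > 0
        se = ts.block_standard_error(series, block_duration=10_000.0,
                                     frame_spacing=1.0)
        expected = np.std([1, 0, 0, 0, 0], ddof=1) / np.sqrt(5)
        assert se == pytest.approx(expected, abs=1e-12)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(InsufficientDataError):
            ts.block_standard_error([1.0] * 15, block_duration=10.0,
                                    frame_spacing=1.0)


class TestRmsdTimeseries:
    def test_reference_frame_zero(self):
        spec = ts.TrajectorySpec(variant="v", temperature="t", n_frames=5,
                                 pair_schedule=[ts.PairSchedule(1, 5, 0.5)], seed=0)
        traj, _ = ts.make_hbond_trajectory(spec)
        series = ts.rmsd_timeseries(traj, traj.frame_structure(0))
        assert series[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotations_give_zero(self):
        from scipy.spatial.transform import Rotation
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=25, seed=8))
        base = sa.coords()
        frames = np.stack([
            base @ Rotation.random(random_state=k).as_matrix().T + k * 0.5
            for k in range(6)
        ])
        traj = ts.Trajectory(sa, frames, 1.0)
        series = ts.rmsd_timeseries(traj, sa)
        assert np.all(series < 1e-9)

    def test_isotropic_noise_matches_analytic_expectation(self):
        # iid Gaussian displacement sigma per coordinate -> RMSD ~ sqrt(3)*sigma
        sigma = 0.02
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=30, seed=1))
        base = sa.coords()
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frames = base + rng.normal(scale=sigma, size=(10,) + base.shape)
            traj = ts.Trajectory(sa, frames, 1.0)
            means.append(ts.rmsd_timeseries(traj, sa).mean())
        assert np.mean(means) == pytest.approx(np.sqrt(3) * sigma, rel=0.10)
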