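"""Alignment, Kabsch superposition, deviation profiles, substitutions."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import thermoseg as ts
from thermoseg.errors import DegenerateGeometryError, ValidationError

from conftest import alignment_score, needleman_wunsch_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestAlignSequences:
    @pytest.mark.parametrize("a,b", [
        ("ANESVISP", "EDELSVSS"),
        ("RAQPGQ", "GATNRA"),
        ("TSTVDTK", "RTSDASQ"),
    ])
    def test_equal_length_segment_pairs_align_without_gaps(self, a, b):
        aln = ts.align_sequences(a, b)
        assert len(aln) == len(a)
        assert "-" not in aln.seq_a + aln.seq_b

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=8),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=8))
    def test_alignment_is_optimal_against_dp_oracle(self, a, b):
        aln = ts.align_sequences(a, b)
        got = alignment_score(aln, BLOSUM62)
        best = needleman_wunsch_score(a, b, BLOSUM62)
        assert got == pytest.approx(best)

    def test_identity_alignment(self):
        aln = ts.align_sequences("ANESVISP", "ANESVISP")
        assert aln.seq_a == aln.seq_b == "ANESVISP"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            ts.align_sequences("A", "")

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValidationError):
            ts.align_sequences("AB1", "AAA")


class TestKabsch:
    def test_identical_sets_identity_rotation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        sup = ts.kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(sup.rotation), 1.0, atol=1e-8)

    def test_construct_and_recover_random_rigid_motion(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            pts = np.random.default_rng(seed).normal(size=(12, 3))
            R = Rotation.random(random_state=seed).as_matrix()
            t = rng.normal(size=3)
            moved = pts @ R.T + t
            sup = ts.kabsch_superpose(pts, moved)
            assert sup.rmsd < 1e-10
            assert np.abs(sup.apply(moved) - pts).max() < 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(7)
        A, B = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        sup = ts.kabsch_superpose(A, B)
        rot, _ = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
        ref = np.sqrt((((B - B.mean(0)) @ rot.as_matrix().T - (A - A.mean(0))) ** 2)
                      .sum() / len(A))
        assert sup.rmsd == pytest.approx(ref, abs=1e-12)

    def test_mirror_image_det_corrected(self):
        # chiral 4-point set: its mirror cannot be superposed by a proper rotation
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirror = pts * np.array([1, 1, -1])
        sup = ts.kabsch_superpose(pts, mirror)
        assert np.isclose(np.linalg.det(sup.rotation), 1.0, atol=1e-8)
        assert sup.rmsd > 0.1
        # the improper branch would fit exactly; the proper branch must not
        rot, _ = Rotation.align_vectors(pts - pts.mean(0), mirror - mirror.mean(0))
        ref = np.sqrt((((mirror - mirror.mean(0)) @ rot.as_matrix().T
                        - (pts - pts.mean(0))) ** 2).sum() / 4)
        assert sup.rmsd == pytest.approx(ref, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ts.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            ts.kabsch_superpose(line, line)


def _identity_alignment(struct):
    seq = ts.extract_sequence(struct, "A")
    return ts.align_sequences(seq.sequence, seq.sequence,
                              seq.numbering, seq.numbering)


class TestDeviationProfile:
    def test_identical_structures_zero_everywhere(self):
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=40, seed=0))
        prof = ts.deviation_profile(sa, sa, _identity_alignment(sa))
        assert np.all(prof.deviations < 1e-12)
        assert prof.segments == []

    def test_planted_segment_recovered_exactly(self):
        spec = ts.StructurePairSpec(length=120,
                                    planted_segments=[(35, 42, 0.5)], seed=2)
        sa, sb, _ = ts.make_structure_pair(spec)
        prof = ts.deviation_profile(sa, sb, _identity_alignment(sa),
                                    threshold=0.3, min_len=6)
        assert [(s.start, s.end) for s in prof.segments] == [(35, 42)]

    def test_rigid_motion_invariance(self):
        spec = ts.StructurePairSpec(length=60, planted_segments=[(20, 27, 0.5)],
                                    background_noise=0.02, seed=3)
        sa, sb, _ = ts.make_structure_pair(spec)
        aln = _identity_alignment(sa)
        base = ts.deviation_profile(sa, sb, aln)
        R = Rotation.random(random_state=5).as_matrix()
        moved = sb.with_coords(sb.coords() @ R.T + np.array([1.0, -2.0, 0.5]))
        prof = ts.deviation_profile(sa, moved, aln)
        assert np.abs(prof.deviations - base.deviations).max() < 1e-9

    def test_segment_calls_monotone_in_threshold(self):
        spec = ts.StructurePairSpec(length=100,
                                    planted_segments=[(30, 40, 0.6), (60, 70, 0.4)],
                                    background_noise=0.03, seed=9)
        sa, sb, _ = ts.make_structure_pair(spec)
        aln = _identity_alignment(sa)
        low = ts.deviation_profile(sa, sb, aln, threshold=0.2, min_len=6)
        high = ts.deviation_profile(sa, sb, aln, threshold=0.35, min_len=6)
        low_cover = {p for s in low.segments for p in range(s.start, s.end + 1)}
        for seg in high.segments:
            assert set(range(seg.start, seg.end + 1)) <= low_cover

    def test_planted_recovery_perfect_across_seeds(self):
        # displacement 2x threshold, background noise 0.05 nm
        hits = 0
        for seed in range(100):
            spec = ts.StructurePairSpec(length=80,
                                        planted_segments=[(30, 37, 0.6)],
                                        background_noise=0.05, seed=seed)
            sa, sb, truth = ts.make_structure_pair(spec)
            prof = ts.deviation_profile(sa, sb, _identity_alignment(sa),
                                        threshold=0.3, min_len=6)
            called = {p for s in prof.segments for p in range(s.start, s.end + 1)}
            expected = set(range(30, 38))
            if called == expected:
                hits += 1
        assert hits == 100  # precision and recall both 1.0


class TestEnumerateSubstitutions:
    def test_segment_one_mismatch_positions(self):
        aln = ts.align_sequences("ANESVISP", "EDELSVSS",
                                 numbering_a=tuple(range(35, 43)),
                                 numbering_b=tuple(range(35, 43)))
        seg = ts.DivergentSegment(35, 42, 8, 0.5)
        subs = ts.enumerate_substitutions(aln, [seg])
        assert subs.positions == (35, 36, 38, 39, 40, 42)

    def test_three_segments_total_eighteen(self, all_18_sites):
        assert len(all_18_sites) == 18

    def test_identical_segment_empty(self):
        aln = ts.align_sequences("RAQPGQ", "RAQPGQ")
        seg = ts.DivergentSegment(1, 6, 6, 0.5)
        assert len(ts.enumerate_substitutions(aln, [seg])) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=6, max_size=12),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_count_equals_hamming_mismatches(self, seq, seed):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        other = "".join(rng.choice(letters) for _ in seq)
        aln = ts.AlignmentPair(seq, other,
                               tuple(range(1, len(seq) + 1)),
                               tuple(range(1, len(seq) + 1)))
        seg = ts.DivergentSegment(1, len(seq), len(seq), 1.0)
        subs = ts.enumerate_substitutions(aln, [seg])
        hamming = sum(x != y for x, y in zip(seq, other))
        assert len(subs) == hamming


class TestResidueMinDistance:
    def test_known_two_atom_distance(self):
        from thermoseg.structure import Atom, Residue, Structure
        r1 = Residue("GLY", 1, "A", [Atom("CA", "C", [0, 0, 0], 1)])
        r2 = Residue("GLY", 2, "A", [Atom("CA", "C", [0, 0, 0.8], 2)])
        s = Structure({"A": [r1, r2]})
        dist, pair = ts.residue_min_distance(s, [1], [2])
        assert dist == pytest.approx(0.8)
        assert pair == ((("A", 1), "CA"), (("A", 2), "CA"))

    def test_matches_exhaustive_pair_scan(self):
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=30, seed=6))
        dist, _ = ts.residue_min_distance(sa, [5, 6], [20, 21])
        atoms_a = [a.coords for k in (5, 6)
                   for a in sa.residue(("A", k)).heavy_atoms()]
        atoms_b = [a.coords for k in (20, 21)
                   for a in sa.residue(("A", k)).heavy_atoms()]
        brute = min(np.linalg.norm(x - y) for x in atoms_a for y in atoms_b)
        assert dist == pytest.approx(brute, abs=1e-12)

    def test_empty_selection_rejected(self):
        sa, _, _ = ts.make_structure_pair(ts.StructurePairSpec(length=20, seed=1))
        with pytest.raises(ValidationError):
            ts.residue_min_distance(sa, [], [1])
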