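"""Homolog structure comparison: alignment, superposition, deviation profile.

The workflow mirrors how divergent regions between a target enzyme and a
thermostable homolog are located: align the two sequences globally, fit the
homolog onto the target with a single rigid (Kabsch) superposition over all
equivalent Cα atoms, measure the per-position Cα–Cα distance, and call
maximal runs of consecutive gap-free positions whose deviation exceeds a
cutoff (default 0.3 nm, minimum run length 6).  Each differing position
inside a called segment is a candidate substitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ChainLookupError, DegenerateGeometryError, ValidationError
from .structure import ResKey, Structure

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"


# ---------------------------------------------------------------------------
# Sequence alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentPair:
    """A global pairwise alignment with per-column residue numbering.

    ``index_a``/``index_b`` hold the author residue number of each column,
    or ``None`` in gap columns.
    """

    seq_a: str
    seq_b: str
    index_a: tuple[int | None, ...]
    index_b: tuple[int | None, ...]

    def __post_init__(self) -> None:
        lengths = {len(self.seq_a), len(self.seq_b), len(self.index_a), len(self.index_b)}
        if len(lengths) != 1:
            raise ValidationError("alignment fields must share one length")
        for ca, cb in zip(self.seq_a, self.seq_b):
            if ca == GAP and cb == GAP:
                raise ValidationError("column with gaps on both sides")

    def __len__(self) -> int:
        return len(self.seq_a)

    def columns(self):
        """Iterate (aa_a, aa_b, pos_a, pos_b) per column."""
        yield from zip(self.seq_a, self.seq_b, self.index_a, self.index_b)


def align_sequences(a: str, b: str,
                    numbering_a: tuple[int, ...] | None = None,
                    numbering_b: tuple[int, ...] | None = None,
                    matrix: str = "BLOSUM62",
                    gap_open: float = -10.0,
                    gap_extend: float = -0.5) -> AlignmentPair:
    """Optimal global alignment of two amino-acid sequences.

    Scoring is BLOSUM62 with affine gaps (open -10, extend -0.5) by
    default.  Numbering defaults to 1..len; pass the structure-derived
    numbering to keep author residue numbers attached to columns.
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValidationError(f"sequence {name} is empty")
        bad = set(seq) - _VALID_AA
        if bad:
            raise ValidationError(f"sequence {name} has non-amino-acid characters: {sorted(bad)}")
    numbering_a = numbering_a or tuple(range(1, len(a) + 1))
    numbering_b = numbering_b or tuple(range(1, len(b) + 1))
    if len(numbering_a) != len(a) or len(numbering_b) != len(b):
        raise ValidationError("numbering length must match sequence length")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    seq_a, seq_b = str(aln[0]), str(aln[1])
    idx = aln.indices  # (2, n_columns), -1 in gap columns
    index_a = tuple(numbering_a[i] if i >= 0 else None for i in idx[0])
    index_b = tuple(numbering_b[i] if i >= 0 else None for i in idx[1])
    return AlignmentPair(seq_a, seq_b, index_a, index_b)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid map x -> rotation @ x + translation taking B onto A."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_fit: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of point set B onto point set A.

    Uses the SVD form of the Kabsch algorithm with the reflection branch
    corrected so the returned rotation is proper (det = +1).  Requires at
    least 3 non-collinear point pairs.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValidationError(f"point sets must both be (n, 3); got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")
    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    H = (B - cen_b).T @ (A - cen_a)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-10 * max(S[0], 1e-300):
        raise DegenerateGeometryError("point set is collinear or coincident; rotation undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b
    diff = (B @ R.T + t) - A
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_fit=n)


# ---------------------------------------------------------------------------
# Deviation profile and segment calling
# ---------------------------------------------------------------------------

@dataclass
class DivergentSegment:
    """A maximal gap-free run of aligned positions deviating beyond cutoff."""

    start: int
    end: int
    length: int
    max_dev: float

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class DeviationProfile:
    positions: tuple[int, ...]            # reference residue numbers
    deviations: np.ndarray                # nm, aligned to positions
    segments: list[DivergentSegment]
    superposition: SuperpositionResult
    ref_residues: tuple[str, ...] = ()    # one-letter, aligned to positions
    hom_positions: tuple[int, ...] = ()
    hom_residues: tuple[str, ...] = ()

    def in_segment(self, position: int) -> bool:
        return any(seg.covers(position) for seg in self.segments)


def _call_segments(positions: list[int], deviations: list[float],
                   contiguous: list[bool], threshold: float,
                   min_len: int) -> list[DivergentSegment]:
    """Maximal runs of >= min_len consecutive columns with deviation > threshold.

    ``contiguous[i]`` marks that column i directly follows column i-1 with
    no intervening gap column; a gap breaks any run.
    """
    segments: list[DivergentSegment] = []
    run: list[int] = []

    def flush():
        if len(run) >= min_len:
            devs = [deviations[i] for i in run]
            segments.append(DivergentSegment(
                start=positions[run[0]], end=positions[run[-1]],
                length=len(run), max_dev=float(max(devs)),
            ))
        run.clear()

    for i in range(len(positions)):
        if deviations[i] > threshold and (not run or contiguous[i]):
            run.append(i)
        else:
            flush()
            if deviations[i] > threshold:
                run.append(i)
    flush()
    return segments


def deviation_profile(struct_a: Structure, struct_b: Structure,
                      aln: AlignmentPair,
                      threshold: float = 0.3, min_len: int = 6,
                      chain_a: str | None = None,
                      chain_b: str | None = None) -> DeviationProfile:
    """Per-aligned-position Cα deviation after one global Kabsch fit.

    All aligned, gap-free columns with a Cα atom on both sides enter a
    single rigid fit of B onto A (no trimming); the profile is then the
    per-column Euclidean Cα–Cα distance on reference numbering, and
    divergent segments are called at ``threshold`` (nm) with minimum run
    length ``min_len``.  Columns missing a Cα are dropped with a warning.
    """
    chain_a = chain_a or next(iter(struct_a.chains))
    chain_b = chain_b or next(iter(struct_b.chains))
    res_a = {r.res_seq: r for r in struct_a.chain(chain_a)}
    res_b = {r.res_seq: r for r in struct_b.chain(chain_b)}

    cols = []  # (pos_a, pos_b, aa_a, aa_b, ca_a, ca_b, gap_before)
    gap_pending = False
    for aa_a, aa_b, pa, pb in aln.columns():
        if pa is None or pb is None:
            gap_pending = True
            continue
        ra, rb = res_a.get(pa), res_b.get(pb)
        ca_a = ra.atom("CA") if ra else None
        ca_b = rb.atom("CA") if rb else None
        if ca_a is None or ca_b is None:
            warnings.warn(f"no Cα for aligned column {pa}/{pb}; dropped")
            gap_pending = True
            continue
        cols.append((pa, pb, aa_a, aa_b, ca_a.coords, ca_b.coords, gap_pending))
        gap_pending = False

    if len(cols) < 3:
        raise DegenerateGeometryError(f"only {len(cols)} usable Cα pairs; need >= 3")

    A = np.array([c[4] for c in cols])
    B = np.array([c[5] for c in cols])
    sup = kabsch_superpose(A, B)
    B_fit = sup.apply(B)
    devs = np.linalg.norm(B_fit - A, axis=1)

    positions = [c[0] for c in cols]
    contiguous = [
        (i > 0) and (not cols[i][6]) and (positions[i] == positions[i - 1] + 1)
        for i in range(len(cols))
    ]
    segments = _call_segments(positions, devs.tolist(), contiguous, threshold, min_len)
    return DeviationProfile(
        positions=tuple(positions),
        deviations=devs,
        segments=segments,
        superposition=sup,
        ref_residues=tuple(c[2] for c in cols),
        hom_positions=tuple(c[1] for c in cols),
        hom_residues=tuple(c[3] for c in cols),
    )


# ---------------------------------------------------------------------------
# Candidate substitutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Substitution:
    position: int        # reference numbering
    residue_a: str       # reference (wild-type) amino acid
    residue_b: str       # homolog amino acid
    source_segment: int  # index into the segment list


@dataclass
class SubstitutionSet:
    entries: list[Substitution] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [e.position for e in self.entries]
        if len(positions) != len(set(positions)):
            raise ValidationError("duplicate substitution positions")
        for e in self.entries:
            if e.residue_a == e.residue_b:
                raise ValidationError(f"position {e.position}: residues identical")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(e.position for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def enumerate_substitutions(aln: AlignmentPair,
                            segments: list[DivergentSegment]) -> SubstitutionSet:
    """One substitution per differing aligned column inside each segment.

    Gap columns inside a segment window are skipped with a warning (a
    substitution requires a one-to-one residue pairing).
    """
    entries: list[Substitution] = []
    for seg_idx, seg in enumerate(segments):
        for aa_a, aa_b, pa, pb in aln.columns():
            if pa is None or pb is None:
                if pa is not None and seg.covers(pa):
                    warnings.warn(f"gap column inside segment {seg.start}-{seg.end}; skipped")
                continue
            if seg.covers(pa) and aa_a != aa_b:
                entries.append(Substitution(pa, aa_a, aa_b, seg_idx))
    return SubstitutionSet(entries=entries)


# ---------------------------------------------------------------------------
# Distances between residue selections
# ---------------------------------------------------------------------------

def residue_min_distance(structure: Structure,
                         set_a: list[ResKey | int],
                         set_b: list[ResKey | int],
                         ) -> tuple[float, tuple[tuple[ResKey, str], tuple[ResKey, str]]]:
    """Minimum heavy-atom distance (nm) between two residue selections.

    Selections are residue keys ``(chain, res_seq)`` or bare residue
    numbers resolved in the first chain.  Returns the distance and the
    closest atom pair as ``((res_key, atom_name), (res_key, atom_name))``.
    """
    def resolve(sel) -> list:
        first_chain = next(iter(structure.chains))
        out = []
        for item in sel:
            key = (first_chain, item) if isinstance(item, int) else item
            out.append(structure.residue(key))
        return out

    if not set_a or not set_b:
        raise ValidationError("both selections must be non-empty")
    residues_a = resolve(set_a)
    residues_b = resolve(set_b)
    best = None
    for ra in residues_a:
        for aa in ra.heavy_atoms():
            for rb in residues_b:
                for ab in rb.heavy_atoms():
                    d = float(np.linalg.norm(aa.coords - ab.coords))
                    if best is None or d < best[0]:
                        best = (d, ((ra.key, aa.name), (rb.key, ab.name)))
    if best is None:
        raise ValidationError("selections contain no heavy atoms")
    return best
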