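"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three input classes the workflow consumes:

* **structure pairs** — an idealized helical Cα-trace backbone duplicated
  with rigid displacements planted on chosen segments plus isotropic
  background noise, so segment calling has exact ground truth;
* **hydrogen-bond trajectories** — multi-frame coordinate sets in which
  prescribed residue pairs realize prescribed occupancies and mean
  simultaneous-bond counts *exactly*, via deterministic seeded frame
  schedules that place donor–hydrogen–acceptor geometry inside or outside
  the criteria frame by frame;
* **kinetics datasets** — Michaelis–Menten curves at 12 substrate
  concentrations spanning 50–2500 μM with optional multiplicative noise.

The "temperature" and "variant" attached to a trajectory are labels only:
no thermodynamics is simulated.  These generators stand in for the
molecular-dynamics stage of the real workflow, whose propagation is out
of scope here; what they preserve is the *statistical* structure the
downstream analyses consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SyntheticSpecError, ValidationError
from .kinetics import KineticsDataset, michaelis_menten
from .structure import Atom, ONE_TO_THREE, Residue, Structure, Trajectory

# ---------------------------------------------------------------------------
# Idealized backbones
# ---------------------------------------------------------------------------

# local backbone offsets (nm) relative to the residue's Cα frame position;
# crude template geometry, adequate for Cα-based analyses
_BACKBONE_OFFSETS = {
    "N": np.array([-0.12, 0.09, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.12, 0.09, 0.0]),
    "O": np.array([0.18, 0.20, 0.0]),
}
_CB_OFFSET = np.array([0.0, -0.15, 0.05])

# α-helical Cα trace parameters: ~0.15 nm rise and 100° turn per residue
_HELIX_RISE = 0.15
_HELIX_RADIUS = 0.23
_HELIX_TURN_DEG = 100.0


def _ca_trace(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.deg2rad(_HELIX_TURN_DEG) * k
    return np.column_stack([
        _HELIX_RISE * k,
        _HELIX_RADIUS * np.cos(phi),
        _HELIX_RADIUS * np.sin(phi),
    ])


def structure_from_sequence(sequence: str, start: int = 1,
                            chain_id: str = "A") -> Structure:
    """An idealized helical backbone (N, CA, C, O, CB) for a sequence.

    Residue numbering starts at ``start``.  Only standard one-letter codes
    are accepted.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise ValidationError(f"non-standard letters: {sorted(bad)}")
    trace = _ca_trace(len(sequence))
    residues = []
    serial = 1
    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE[letter]
        atoms = []
        for name, off in _BACKBONE_OFFSETS.items():
            atoms.append(Atom(name, name[0], trace[i] + off, serial))
            serial += 1
        if res_name != "GLY":
            atoms.append(Atom("CB", "C", trace[i] + _CB_OFFSET, serial))
            serial += 1
        residues.append(Residue(res_name, start + i, chain_id, atoms))
    return Structure({chain_id: residues})


# ---------------------------------------------------------------------------
# Structure pairs with planted divergent segments
# ---------------------------------------------------------------------------

@dataclass
class StructurePairSpec:
    """Recipe for a homolog-like structure pair with planted divergence."""

    length: int
    planted_segments: list[tuple[int, int, float]] = field(default_factory=list)
    background_noise: float = 0.0   # nm, isotropic Gaussian on structure B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValidationError("length must be >= 20")
        spans = []
        for start, end, disp in self.planted_segments:
            if not (1 <= start <= end <= self.length):
                raise ValidationError(f"segment {start}-{end} outside 1..{self.length}")
            if not disp > 0:
                raise ValidationError("displacement must be > 0")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise SyntheticSpecError(f"overlapping segments at {s2}")
        if self.background_noise < 0:
            raise ValidationError("background_noise must be >= 0")


def make_structure_pair(spec: StructurePairSpec,
                        ) -> tuple[Structure, Structure, list[tuple[int, int]]]:
    """A structure and its displaced copy, plus planted segment truth.

    Structure B equals A with each planted segment's residues rigidly
    shifted by the requested magnitude (seeded random direction) and all
    atoms jittered by the background noise.  Sequences are identical, so
    the alignment is the identity and every aligned position is a valid
    Cα pair.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(ONE_TO_THREE))
    sequence = "".join(rng.choice(letters, size=spec.length))
    struct_a = structure_from_sequence(sequence)
    coords = struct_a.coords().copy()

    res_of_atom = np.array([res.res_seq for res, _ in struct_a.atoms()])
    for start, end, disp in spec.planted_segments:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mask = (res_of_atom >= start) & (res_of_atom <= end)
        coords[mask] += disp * direction
    if spec.background_noise > 0:
        coords += rng.normal(scale=spec.background_noise, size=coords.shape)
    struct_b = struct_a.with_coords(coords)
    truth = [(s, e) for s, e, _ in spec.planted_segments]
    return struct_a, struct_b, truth


# ---------------------------------------------------------------------------
# Trajectories realizing prescribed H-bond occupancies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairSchedule:
    """Target occupancy/mean count for one donor->acceptor residue pair."""

    donor_res: int
    acceptor_res: int
    occupancy: float
    mean_count: float | None = None   # defaults to occupancy (single triple)


@dataclass
class TrajectorySpec:
    variant: str
    temperature: str
    n_frames: int
    pair_schedule: list[PairSchedule]
    frame_spacing: float = 1.0  # ps
    seed: int = 0
    chain_id: str = "A"
    stochastic: bool = False    # Bernoulli frames instead of exact schedules

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        for ps in self.pair_schedule:
            if not (0.0 <= ps.occupancy <= 1.0):
                raise ValidationError(f"occupancy {ps.occupancy} outside [0, 1]")
            mc = ps.mean_count if ps.mean_count is not None else ps.occupancy
            if mc < ps.occupancy - 1e-12:
                raise SyntheticSpecError("mean_count below occupancy")
            if mc > 2 * ps.occupancy + 1e-12:
                raise SyntheticSpecError(
                    f"pair {ps.donor_res}->{ps.acceptor_res}: mean_count {mc} "
                    f"needs a third simultaneous triple (> 2x occupancy)"
                )
            if ps.donor_res == ps.acceptor_res:
                raise ValidationError("donor and acceptor residue coincide")


# asparagine-like residue: two donor slots (N-H, ND2-HD21) and two pure
# acceptor slots (O, OD1); acceptors never donate, so a relocated acceptor
# atom cannot emit a reverse bond of its own
_DONOR_SLOTS = (("N", "H"), ("ND2", "HD21"))
_ACCEPTOR_SLOTS = ("O", "OD1")

_RESIDUE_SPACING = 4.0   # nm between residue anchors; >> criteria cutoff
_LOCAL = {
    "N": np.array([0.0, 0.0, 0.0]),
    "H": np.array([0.10, 0.0, 0.0]),
    "CA": np.array([0.20, -0.20, 0.0]),
    "C": np.array([0.40, -0.20, 0.0]),
    "O": np.array([0.50, -0.10, 0.0]),
    "CB": np.array([0.20, -0.35, 0.0]),
    "ND2": np.array([0.0, 1.0, 0.0]),
    "HD21": np.array([0.10, 1.0, 0.0]),
    "OD1": np.array([0.0, -1.0, 0.0]),
}
_BONDED_OFFSET = np.array([0.30, 0.0, 0.0])     # D-A 0.30 nm, H-D-A angle 0°
_UNBONDED_OFFSET = np.array([0.45, 0.0, 0.0])   # fails the distance criterion


def make_hbond_trajectory(spec: TrajectorySpec,
                          ) -> tuple[Trajectory, dict]:
    """Build a trajectory whose detected pair statistics equal the spec.

    Each scheduled pair is realized by a primary N–H···O triple placed in
    exactly ``round(occupancy * n_frames)`` frames (seeded permutation
    schedule) and, where mean_count exceeds occupancy, a secondary
    OG–HG···OG triple on a subset of those frames.  In unscheduled frames
    the acceptor sits at 0.45 nm, outside the distance criterion.  Returns
    the trajectory and a ground-truth dict keyed by canonical pair key.
    """
    res_ids = sorted({r for ps in spec.pair_schedule
                      for r in (ps.donor_res, ps.acceptor_res)})
    if not res_ids:
        raise SyntheticSpecError("empty pair schedule")
    anchors = {rid: np.array([_RESIDUE_SPACING * i, 0.0, 0.0])
               for i, rid in enumerate(res_ids)}

    residues = []
    serial = 1
    atom_pos: dict[tuple[int, str], int] = {}
    flat = 0
    for rid in res_ids:
        atoms = []
        for name, off in _LOCAL.items():
            element = "H" if name.startswith("H") else name[0]
            atoms.append(Atom(name, element, anchors[rid] + off, serial))
            atom_pos[(rid, name)] = flat
            serial += 1
            flat += 1
        residues.append(Residue("ASN", rid, spec.chain_id, atoms))
    topology = Structure({spec.chain_id: residues})
    base = topology.coords()

    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    frames = np.tile(base, (n, 1, 1))
    used: dict[int, set[str]] = {rid: set() for rid in res_ids}
    truth: dict = {}

    def take_donor(rid: int) -> tuple[str, str]:
        for heavy, hyd in _DONOR_SLOTS:
            if heavy not in used[rid]:
                used[rid].add(heavy)
                return heavy, hyd
        raise SyntheticSpecError(f"residue {rid}: donor atoms exhausted")

    def take_acceptor(rid: int, avoid_backbone_o: bool = False) -> str:
        order = _ACCEPTOR_SLOTS[::-1] if avoid_backbone_o else _ACCEPTOR_SLOTS
        for name in order:
            if name not in used[rid]:
                used[rid].add(name)
                return name
        raise SyntheticSpecError(f"residue {rid}: acceptor atoms exhausted")

    for ps in spec.pair_schedule:
        mc = ps.mean_count if ps.mean_count is not None else ps.occupancy
        if spec.stochastic:
            bonded1 = np.nonzero(rng.random(n) < ps.occupancy)[0]
            p2 = 0.0 if ps.occupancy == 0 else min((mc - ps.occupancy) / ps.occupancy, 1.0)
            bonded2 = bonded1[rng.random(bonded1.size) < p2]
        else:
            n1 = int(round(ps.occupancy * n))
            n2 = int(round(mc * n)) - n1
            perm = rng.permutation(n)
            bonded1 = np.sort(perm[:n1])
            bonded2 = bonded1[:n2]
        # a donor N one position after the acceptor's backbone O would hit
        # the detector's peptide-bond exclusion; route around it via OG
        peptide_adjacent = ps.donor_res == ps.acceptor_res + 1
        triples = [(take_donor(ps.donor_res),
                    take_acceptor(ps.acceptor_res, avoid_backbone_o=peptide_adjacent),
                    bonded1)]
        if bonded2.size:
            triples.append((take_donor(ps.donor_res),
                            take_acceptor(ps.acceptor_res), bonded2))
        for (heavy, _hyd), acc_name, bonded in triples:
            d_idx = atom_pos[(ps.donor_res, heavy)]
            a_idx = atom_pos[(ps.acceptor_res, acc_name)]
            d_pos = base[d_idx]
            frames[:, a_idx, :] = d_pos + _UNBONDED_OFFSET
            frames[bonded, a_idx, :] = d_pos + _BONDED_OFFSET
        key_d = (spec.chain_id, ps.donor_res)
        key_a = (spec.chain_id, ps.acceptor_res)
        key = (key_d, key_a) if key_d <= key_a else (key_a, key_d)
        truth[key] = {
            "occupancy": bonded1.size / n,
            "mean_count": (bonded1.size + bonded2.size) / n,
        }
    traj = Trajectory(topology=topology, frames=frames,
                      frame_spacing=spec.frame_spacing)
    return traj, truth


# ---------------------------------------------------------------------------
# Kinetics data
# ---------------------------------------------------------------------------

#: 12 substrate concentrations spanning 0.05-2.5 mM, in μM
DEFAULT_CONCENTRATIONS_UM = tuple(np.linspace(50.0, 2500.0, 12))


def make_kinetics_dataset(Km: float, Vmax: float,
                          concentrations=None,
                          noise_cv: float = 0.0,
                          seed: int = 0,
                          enzyme: str = "synthetic") -> KineticsDataset:
    """Michaelis–Menten rates with multiplicative Gaussian noise.

    ``noise_cv`` is the coefficient of variation of the noise; a draw that
    would push a rate negative is truncated at zero with a warning.
    """
    if not (Km > 0 and Vmax > 0):
        raise ValidationError("Km and Vmax must be positive")
    S = np.asarray(
        DEFAULT_CONCENTRATIONS_UM if concentrations is None else concentrations,
        dtype=float,
    )
    v = michaelis_menten(S, Km, Vmax)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_cv * rng.standard_normal(S.size))
        if np.any(v < 0):
            warnings.warn("negative noisy rate truncated at 0")
            v = np.clip(v, 0.0, None)
    return KineticsDataset(substrate_conc=S, rate=v, enzyme=enzyme)
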