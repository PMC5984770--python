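"""Geometric hydrogen-bond detection and trajectory occupancy statistics.

A hydrogen bond D–H···A is counted in a frame when the donor–acceptor
distance is at most 0.35 nm and the hydrogen–donor–acceptor angle (vertex
at the donor heavy atom, between the D→H and D→A directions; 0° = linear)
is at most 30°.  Per residue pair the trajectory yields

* **occupancy** — the fraction of frames in which the pair forms at least
  one bond (any donor/hydrogen/acceptor triple), and
* **mean_count** — the average number of *distinct* simultaneous
  donor–acceptor bonds per frame, which can exceed 1 for multivalent
  contacts such as bidentate side chains.

Uncertainty on the per-frame bond count uses block averaging: the series
is cut into consecutive fixed-duration blocks (default 10 ns) and the
standard error of the block means is reported, which is robust to the
strong autocorrelation of bonded/unbonded runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .compare import kabsch_superpose
from .errors import (
    ChainLookupError,
    ConfigurationError,
    InsufficientDataError,
    TrajectoryShapeError,
    ValidationError,
)
from .structure import DonorAcceptorMap, ResKey, Structure, Trajectory

PairKey = tuple[ResKey, ResKey]


def make_pair_key(a: ResKey, b: ResKey) -> PairKey:
    """Canonical (sorted) residue-pair key; WT/mutant name changes at a
    site do not alter the key because it is positional."""
    return (a, b) if a <= b else (b, a)


@dataclass
class HBondCriteria:
    """Geometric criteria: D–A distance cutoff (nm) and H–D–A angle cutoff
    (degrees, vertex at the donor)."""

    max_da_dist: float = 0.35
    max_hda_angle: float = 30.0

    def __post_init__(self) -> None:
        if not (self.max_da_dist > 0):
            raise ValidationError("max_da_dist must be > 0")
        if not (0 < self.max_hda_angle < 90):
            raise ValidationError("max_hda_angle must be in (0, 90)")


class HBondEvent(NamedTuple):
    frame: int
    donor: tuple[ResKey, str]
    hydrogen: str
    acceptor: tuple[ResKey, str]


@dataclass
class PairStats:
    """Occupancy statistics for one residue pair in one (variant,
    temperature) simulation condition."""

    pair: PairKey
    variant: str
    temperature: str
    n_frames: int
    occupancy: float
    mean_count: float
    block_se: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.mean_count < self.occupancy - 1e-12:
            raise ValidationError("mean_count below occupancy")
        if np.isfinite(self.block_se) and self.block_se < 0:
            raise ValidationError("block_se must be >= 0")


def _excluded(donor_res: ResKey, donor_atom: str,
              acc_res: ResKey, acc_atom: str) -> bool:
    """Bonded-neighbour exclusion rule.

    Intra-residue pairs are never hydrogen bonds here; across a peptide
    bond, the amide N of residue i+1 and the carbonyl O of residue i are
    1–3 neighbours through the carbonyl carbon and are likewise excluded.
    """
    if donor_res == acc_res:
        return True
    same_chain = donor_res[0] == acc_res[0]
    if same_chain and donor_atom == "N" and acc_atom == "O" \
            and donor_res[1] == acc_res[1] + 1:
        return True
    return False


def detect_frame_hbonds(topology: Structure,
                        frame_coords: np.ndarray,
                        damap: DonorAcceptorMap,
                        criteria: HBondCriteria = HBondCriteria(),
                        frame_index: int = 0) -> list[HBondEvent]:
    """All qualifying D–H···A triples in one frame.

    One event is emitted per (donor heavy atom, hydrogen, acceptor) triple
    meeting both criteria; a donor with two amide hydrogens can therefore
    produce two events to the same acceptor.  Donors whose hydrogens have
    no coordinates raise a configuration error.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    index = topology.atom_index()

    acc_entries = []
    for res_key, atom in damap.acceptors:
        i = index.get((res_key[0], res_key[1], atom))
        if i is not None:
            acc_entries.append((res_key, atom, i))
    if not acc_entries:
        return []
    acc_pos = frame_coords[[e[2] for e in acc_entries]]

    cos_cut = np.cos(np.deg2rad(criteria.max_hda_angle))
    events: list[HBondEvent] = []
    for res_key, heavy, hydrogens in damap.donors:
        di = index.get((res_key[0], res_key[1], heavy))
        if di is None:
            continue
        h_idx = []
        for h in hydrogens:
            hi = index.get((res_key[0], res_key[1], h))
            if hi is not None:
                h_idx.append((h, hi))
        if not h_idx:
            raise ConfigurationError(
                f"donor {heavy} of residue {res_key} has no hydrogen coordinates"
            )
        d = frame_coords[di]
        da = acc_pos - d
        dist = np.linalg.norm(da, axis=1)
        close = np.nonzero(dist <= criteria.max_da_dist)[0]
        if close.size == 0:
            continue
        for h_name, hi in h_idx:
            dh = frame_coords[hi] - d
            dh_norm = np.linalg.norm(dh)
            if dh_norm == 0:
                continue
            for j in close:
                acc_res, acc_atom, ai = acc_entries[j]
                if ai == di or _excluded(res_key, heavy, acc_res, acc_atom):
                    continue
                if dist[j] == 0:
                    continue
                cos_angle = float(np.dot(dh, da[j]) / (dh_norm * dist[j]))
                if cos_angle >= cos_cut - 1e-12:
                    events.append(HBondEvent(
                        frame=frame_index,
                        donor=(res_key, heavy),
                        hydrogen=h_name,
                        acceptor=(acc_res, acc_atom),
                    ))
    return events


def per_frame_pair_counts(traj: Trajectory, damap: DonorAcceptorMap,
                          criteria: HBondCriteria = HBondCriteria(),
                          ) -> dict[PairKey, np.ndarray]:
    """Distinct-bond counts per frame for every residue pair with events."""
    counts: dict[PairKey, np.ndarray] = {}
    n = traj.n_frames
    for f in range(n):
        events = detect_frame_hbonds(traj.topology, traj.frames[f], damap,
                                     criteria, frame_index=f)
        seen: dict[PairKey, set] = {}
        for ev in events:
            key = make_pair_key(ev.donor[0], ev.acceptor[0])
            seen.setdefault(key, set()).add((ev.donor, ev.hydrogen, ev.acceptor))
        for key, triples in seen.items():
            if key not in counts:
                counts[key] = np.zeros(n)
            counts[key][f] = len(triples)
    return counts


def block_standard_error(per_frame_counts: Sequence[float],
                         block_duration: float,
                         frame_spacing: float) -> float:
    """Standard error of block means for an autocorrelated series.

    The series is partitioned into consecutive blocks of ``block_duration``
    (ps); a trailing partial block is dropped with a warning.  Requires at
    least 2 full blocks.
    """
    series = np.asarray(per_frame_counts, dtype=float)
    frames_per_block = int(round(block_duration / frame_spacing))
    if frames_per_block < 1:
        raise ValidationError("block shorter than one frame")
    n_blocks = series.size // frames_per_block
    if n_blocks < 2:
        raise InsufficientDataError(
            f"only {n_blocks} full block(s) of {frames_per_block} frames; need >= 2"
        )
    if series.size % frames_per_block:
        warnings.warn("trailing partial block dropped")
    used = series[: n_blocks * frames_per_block]
    block_means = used.reshape(n_blocks, frames_per_block).mean(axis=1)
    return float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))


def pair_occupancy_stats(traj: Trajectory, damap: DonorAcceptorMap,
                         criteria: HBondCriteria = HBondCriteria(),
                         pairs: Literal["all"] | Iterable[PairKey] = "all",
                         variant: str = "", temperature: str = "",
                         block_duration: float = 10_000.0,
                         include_empty: bool = False,
                         ) -> dict[PairKey, PairStats]:
    """Occupancy, mean simultaneous-bond count and block SE per pair.

    ``occupancy`` counts a frame once if the pair forms >= 1 bond;
    ``mean_count`` averages the number of distinct simultaneous bonds.
    Pairs with no events are omitted unless explicitly requested.  The
    block SE uses 10-ns blocks by default and is NaN (with a warning) when
    the trajectory is too short for two full blocks.
    """
    if traj.n_frames == 0:
        raise ValidationError("empty trajectory")
    requested: list[PairKey] | None = None
    if pairs != "all":
        requested = [make_pair_key(a, b) for a, b in pairs]
        for key in requested:
            for res_key in key:
                traj.topology.residue(res_key)  # raises ChainLookupError
    counts = per_frame_pair_counts(traj, damap, criteria)
    n = traj.n_frames

    keys: list[PairKey]
    if requested is not None:
        keys = requested
    elif include_empty:
        keys = sorted(counts)
    else:
        keys = sorted(k for k, v in counts.items() if v.any())

    out: dict[PairKey, PairStats] = {}
    for key in keys:
        series = counts.get(key, np.zeros(n))
        if requested is None and not include_empty and not series.any():
            continue
        try:
            se = block_standard_error(series, block_duration, traj.frame_spacing)
        except InsufficientDataError:
            warnings.warn(f"pair {key}: too few frames for block SE; reporting NaN")
            se = float("nan")
        out[key] = PairStats(
            pair=key, variant=variant, temperature=temperature, n_frames=n,
            occupancy=float((series > 0).mean()),
            mean_count=float(series.mean()),
            block_se=se,
        )
    return out


def rmsd_timeseries(traj: Trajectory, reference: Structure,
                    selection: Literal["heavy", "ca"] = "heavy") -> np.ndarray:
    """Per-frame RMSD (nm) to a reference after Kabsch fitting each frame.

    The fit and the measurement use the same atom selection, matched by
    (chain, residue number, atom name).
    """
    ref_index = reference.atom_index()
    sel_pairs = []  # (traj_flat_idx, ref_coords)
    for i, (res, atom) in enumerate(traj.topology.atoms()):
        if selection == "heavy" and atom.is_hydrogen:
            continue
        if selection == "ca" and atom.name != "CA":
            continue
        ref_i = ref_index.get((res.chain_id, res.res_seq, atom.name))
        if ref_i is None:
            raise TrajectoryShapeError(
                f"atom {atom.name} of {res.chain_id}/{res.res_seq} missing from reference"
            )
        sel_pairs.append((i, ref_i))
    if len(sel_pairs) < 3:
        raise ValidationError("selection resolves to fewer than 3 atoms")
    traj_idx = np.array([p[0] for p in sel_pairs])
    ref_coords = reference.coords()[[p[1] for p in sel_pairs]]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(ref_coords, traj.frames[f][traj_idx])
        out[f] = sup.rmsd
    return out
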