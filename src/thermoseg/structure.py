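"""Structure and trajectory containers with PDB I/O.

All coordinates are stored in **nanometres**; PDB files carry ångströms and
the conversion happens once at the I/O boundary.  Structures are plain
residue/atom trees (sufficient for the geometric analyses here), parsed and
written through biotite so the fixed-width PDB conventions — altloc
resolution, element inference, multi-model files — are handled by a
maintained reader.

A multi-model PDB file doubles as the native trajectory carrier: one MODEL
per frame over a fixed topology, which is how snapshot series are exchanged
without a binary trajectory format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from .errors import (
    ChainLookupError,
    EmptyStructureError,
    PDBParseError,
    TrajectoryShapeError,
    ValidationError,
)

ANGSTROM_PER_NM = 10.0

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "SOL", "DOD"}

#: residue key used throughout the package: (chain_id, res_seq)
ResKey = tuple[str, int]


@dataclass
class Atom:
    """A single atom: name, element, position (nm) and serial id."""

    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValidationError(f"atom {self.name!r}: empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Residue:
    """An amino-acid residue identified by author numbering within a chain."""

    res_name: str
    res_seq: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.res_seq)

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


class ChainSequence(NamedTuple):
    """One-letter sequence with the author residue number of each position."""

    sequence: str
    numbering: tuple[int, ...]


@dataclass
class Structure:
    """An ordered collection of chains of residues.

    Chain order and residue order follow the source file.  The flattened
    atom order defined by :meth:`atoms` is the contract shared with
    :class:`Trajectory` frames.
    """

    chains: dict[str, list[Residue]]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError("structure has no chains")

    # -- iteration -------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    # -- lookup ----------------------------------------------------------
    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ChainLookupError(f"no chain {chain_id!r}") from None

    def residue(self, key: ResKey) -> Residue:
        for res in self.chain(key[0]):
            if res.res_seq == key[1]:
                return res
        raise ChainLookupError(f"no residue {key[1]} in chain {key[0]!r}")

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        """Map (chain_id, res_seq, atom_name) -> flat atom position."""
        return {
            (res.chain_id, res.res_seq, atom.name): i
            for i, (res, atom) in enumerate(self.atoms())
        }

    def coords(self) -> np.ndarray:
        """All coordinates as an (n_atoms, 3) array in nm, in flat order."""
        return np.array([a.coords for _, a in self.atoms()], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this topology carrying replacement coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TrajectoryShapeError(
                f"expected ({self.n_atoms}, 3) coordinates, got {coords.shape}"
            )
        chains: dict[str, list[Residue]] = {}
        i = 0
        for cid, chain in self.chains.items():
            new_chain = []
            for res in chain:
                new_atoms = []
                for atom in res.atoms:
                    new_atoms.append(
                        Atom(atom.name, atom.element, coords[i], atom.serial)
                    )
                    i += 1
                new_chain.append(Residue(res.res_name, res.res_seq, cid, new_atoms))
            chains[cid] = new_chain
        return Structure(chains, title=self.title)


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in nm; ``frame_spacing`` is
    the time between consecutive frames in ps.
    """

    topology: Structure
    frames: np.ndarray
    frame_spacing: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryShapeError(f"frames must be (n, atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TrajectoryShapeError(
                f"frames carry {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if not self.frame_spacing > 0:
            raise ValidationError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _locate_bad_atom_line(path: str) -> int | None:
    """Best-effort scan for the first unparseable ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        int(line[22:26])
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def _atom_array_to_structure(arr: "struc.AtomArray", title: str = "",
                             include_hetero: bool = False,
                             keep_waters: bool = False) -> Structure:
    mask = np.ones(arr.array_length(), dtype=bool)
    if not include_hetero:
        mask &= ~arr.hetero
    if not keep_waters:
        mask &= ~np.isin(arr.res_name, list(_WATER_NAMES))
    arr = arr[mask]
    chains: dict[str, list[Residue]] = {}
    current: Residue | None = None
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        rid = int(arr.res_id[i])
        rname = str(arr.res_name[i])
        if current is None or current.chain_id != cid or current.res_seq != rid:
            current = Residue(rname, rid, cid, [])
            chains.setdefault(cid, []).append(current)
        element = str(arr.element[i]) or str(arr.atom_name[i])[0]
        current.atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=element,
                coords=np.asarray(arr.coord[i], dtype=float) / ANGSTROM_PER_NM,
                serial=i + 1,
            )
        )
    if not chains or not any(r.is_standard for c in chains.values() for r in c):
        raise EmptyStructureError("no standard residues after filtering")
    return Structure(chains, title=title)


def read_pdb(path: str, include_hetero: bool = False,
             keep_waters: bool = False) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    Coordinates are converted Å -> nm.  HETATM records and waters are
    excluded unless requested.  When alternate locations are present the
    highest-occupancy conformer is kept.
    """
    try:
        pdb_file = pdb_io.PDBFile.read(path)
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except EmptyStructureError:
        raise
    except Exception as exc:  # biotite raises several concrete types
        lineno = _locate_bad_atom_line(path)
        if lineno is not None:
            raise PDBParseError(f"malformed ATOM record at line {lineno} of {path}") from exc
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    return _atom_array_to_structure(arr, title="",
                                    include_hetero=include_hetero,
                                    keep_waters=keep_waters)


def _model_atom_counts(path: str) -> list[int]:
    counts: list[int] = []
    n = 0
    seen_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                seen_model = True
                n = 0
            elif line.startswith("ENDMDL"):
                counts.append(n)
            elif line.startswith(("ATOM", "HETATM")):
                n += 1
    if not seen_model:
        counts = [n]
    return counts


def read_trajectory(path: str, frame_spacing: float,
                    include_hetero: bool = False,
                    keep_waters: bool = False) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (one frame per MODEL).

    Topology is taken from model 1.  A single-model file yields a valid
    one-frame trajectory.
    """
    try:
        pdb_file = pdb_io.PDBFile.read(path)
        stack = pdb_file.get_structure(model=None, altloc="occupancy")
    except Exception as exc:
        counts = _model_atom_counts(path)
        if len(set(counts)) > 1:
            bad = next(i for i, c in enumerate(counts) if c != counts[0])
            raise TrajectoryShapeError(
                f"model {bad + 1} has {counts[bad]} atoms, model 1 has {counts[0]}"
            ) from exc
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    first = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    topology = _atom_array_to_structure(
        first, include_hetero=include_hetero, keep_waters=keep_waters
    )
    # rebuild the kept-atom mask so frames match the filtered topology
    mask = np.ones(first.array_length(), dtype=bool)
    if not include_hetero:
        mask &= ~first.hetero
    if not keep_waters:
        mask &= ~np.isin(first.res_name, list(_WATER_NAMES))
    frames = np.asarray(stack.coord, dtype=float)[:, mask, :] / ANGSTROM_PER_NM
    return Trajectory(topology=topology, frames=frames, frame_spacing=frame_spacing)


def _structure_to_atom_array(structure: Structure) -> "struc.AtomArray":
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    coord = np.empty((n, 3))
    for i, (res, atom) in enumerate(structure.atoms()):
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.res_seq
        arr.res_name[i] = res.res_name
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element.upper()
        arr.hetero[i] = not res.is_standard
        coord[i] = atom.coords * ANGSTROM_PER_NM
    arr.coord = coord
    return arr


def write_pdb(structure: Structure, path: str) -> None:
    """Write a structure as a single-model PDB file (nm -> Å)."""
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(_structure_to_atom_array(structure))
    pdb_file.write(path)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB file."""
    template = _structure_to_atom_array(traj.topology)
    stack = struc.AtomArrayStack(traj.n_frames, template.array_length())
    for annot in template.get_annotation_categories():
        stack.set_annotation(annot, template.get_annotation(annot))
    stack.coord = traj.frames * ANGSTROM_PER_NM
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def extract_sequence(structure: Structure, chain_id: str) -> ChainSequence:
    """One-letter sequence of a chain with per-position author numbering.

    Nonstandard residues are emitted as ``'X'`` so downstream alignment
    keeps a column for them.
    """
    chain = structure.chain(chain_id)
    seq = "".join(res.one_letter for res in chain)
    numbering = tuple(res.res_seq for res in chain)
    return ChainSequence(seq, numbering)


def write_fasta(records: Iterable[tuple[str, str]], path: str) -> None:
    """Write (header, sequence) records as FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Hydrogen-bond donor / acceptor templates
# ---------------------------------------------------------------------------

class DonorEntry(NamedTuple):
    res_key: ResKey
    heavy_atom: str
    hydrogens: tuple[str, ...]


class AcceptorEntry(NamedTuple):
    res_key: ResKey
    atom: str


@dataclass
class DonorAcceptorMap:
    """Template-assigned hydrogen-bond donors and acceptors.

    Donor heavy atoms and acceptors are restricted to N and O; every donor
    carries at least one hydrogen name.
    """

    donors: list[DonorEntry]
    acceptors: list[AcceptorEntry]

    def __post_init__(self) -> None:
        for d in self.donors:
            if d.heavy_atom[0] not in "NO":
                raise ValidationError(f"donor {d.heavy_atom} is not N/O")
            if not d.hydrogens:
                raise ValidationError(f"donor {d.heavy_atom} has no hydrogens")
        for a in self.acceptors:
            if a.atom[0] not in "NO":
                raise ValidationError(f"acceptor {a.atom} is not N/O")

    @property
    def donor_keys(self) -> set[tuple[ResKey, str]]:
        return {(d.res_key, d.heavy_atom) for d in self.donors}

    @property
    def acceptor_keys(self) -> set[tuple[ResKey, str]]:
        return {(a.res_key, a.atom) for a in self.acceptors}


# amide backbone hydrogen names seen in practice (terminal H1..H3 included)
_BACKBONE_H = ("H", "HN", "H1", "H2", "H3")

_SIDECHAIN_DONORS: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {
    "SER": (("OG", ("HG",)),),
    "THR": (("OG1", ("HG1",)),),
    "TYR": (("OH", ("HH",)),),
    "ASN": (("ND2", ("HD21", "HD22")),),
    "GLN": (("NE2", ("HE21", "HE22")),),
    "LYS": (("NZ", ("HZ1", "HZ2", "HZ3")),),
    "ARG": (("NE", ("HE",)), ("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))),
    "TRP": (("NE1", ("HE1",)),),
}

_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
}

_HIS_DONOR_H = {"ND1": ("HD1",), "NE2": ("HE2",)}

#: maximum covalent D-H distance used to confirm hydrogen attachment, nm
MAX_DH_BOND = 0.12


def _resolve_hydrogens(res: Residue, heavy: Atom,
                       template_names: tuple[str, ...],
                       hydrogens_present: bool) -> tuple[str, ...]:
    if hydrogens_present:
        by_distance = tuple(
            a.name for a in res.atoms
            if a.is_hydrogen and np.linalg.norm(a.coords - heavy.coords) < MAX_DH_BOND
        )
        if by_distance:
            return by_distance
        # fall back on template naming if distance search found nothing
        by_name = tuple(n for n in template_names if res.atom(n) is not None)
        return by_name
    return template_names


def assign_donors_acceptors(structure: Structure,
                            hydrogens_present: bool = False,
                            include_sulfur: bool = False,
                            his_donor_overrides: dict[ResKey, tuple[str, ...]] | None = None,
                            ) -> DonorAcceptorMap:
    """Assign donors/acceptors from amino-acid templates.

    Backbone: the amide N donates (except proline, which has no amide H)
    and the carbonyl O accepts.  Side chains follow the standard templates
    (hydroxyls donate and accept; Asn/Gln amides donate via N and accept
    via O; Lys/Arg/Trp nitrogens donate; carboxylates accept).  Histidine
    ring nitrogens accept by default and additionally donate only where an
    explicit per-residue protonation override names the protonated atom(s),
    since protonation states are input, not predicted.

    With ``hydrogens_present`` the hydrogen attached to each donor is
    confirmed geometrically (D-H < 0.12 nm), template names serving as a
    fallback; a donor whose hydrogen cannot be resolved at all is dropped
    with a warning.  Sulfur chemistry (Cys SG, Met SD) is off by default.
    """
    his_donor_overrides = his_donor_overrides or {}
    donors: list[DonorEntry] = []
    acceptors: list[AcceptorEntry] = []
    for res in structure.residues():
        if not res.is_standard:
            continue
        key = res.key
        # backbone
        n_atom = res.atom("N")
        if n_atom is not None and res.res_name != "PRO":
            hyds = _resolve_hydrogens(res, n_atom, _BACKBONE_H, hydrogens_present)
            if hyds:
                donors.append(DonorEntry(key, "N", hyds))
            elif hydrogens_present:
                warnings.warn(f"donor N of {key} has no resolvable hydrogen; dropped")
        for bb_acc in ("O", "OXT"):
            if res.atom(bb_acc) is not None:
                acceptors.append(AcceptorEntry(key, bb_acc))
        # side chain donors
        entries = list(_SIDECHAIN_DONORS.get(res.res_name, ()))
        if res.res_name == "HIS":
            for atom_name in his_donor_overrides.get(key, ()):
                entries.append((atom_name, _HIS_DONOR_H[atom_name]))
        if include_sulfur and res.res_name == "CYS" and res.atom("SG") is not None:
            entries.append(("SG", ("HG",)))
        for heavy_name, template_h in entries:
            heavy = res.atom(heavy_name)
            if heavy is None:
                continue
            hyds = _resolve_hydrogens(res, heavy, template_h, hydrogens_present)
            if hyds:
                donors.append(DonorEntry(key, heavy_name, hyds))
            elif hydrogens_present:
                warnings.warn(
                    f"donor {heavy_name} of {key} has no resolvable hydrogen; dropped"
                )
        # side chain acceptors
        for acc_name in _SIDECHAIN_ACCEPTORS.get(res.res_name, ()):
            if res.atom(acc_name) is not None:
                acceptors.append(AcceptorEntry(key, acc_name))
        if include_sulfur and res.res_name == "MET" and res.atom("SD") is not None:
            acceptors.append(AcceptorEntry(key, "SD"))
    if include_sulfur:
        # bypass the N/O invariant check for the sulfur extension
        damap = DonorAcceptorMap.__new__(DonorAcceptorMap)
        damap.donors = donors
        damap.acceptors = acceptors
        return damap
    return DonorAcceptorMap(donors=donors, acceptors=acceptors)
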