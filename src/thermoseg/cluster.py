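"""Pairwise-RMSD conformational clustering of trajectory snapshots.

Implements the neighbour-count (Daura/GROMOS) algorithm on a pairwise
RMSD matrix: the frame with the most neighbours within the cutoff seeds a
cluster that absorbs its neighbours, the cluster is removed, and the scan
repeats on the remainder.  Cluster centers double as representative
structures for rendering interaction networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .compare import kabsch_superpose
from .errors import ChainLookupError, ValidationError
from .structure import Structure, Trajectory


@dataclass
class ClusterResult:
    """Cluster assignment over frames; ids are ordered by descending size
    (ties by lower center index)."""

    assignments: dict[int, int]   # frame index -> cluster id
    centers: dict[int, int]       # cluster id -> frame index
    cutoff: float
    sizes: dict[int, int]

    def __post_init__(self) -> None:
        if sum(self.sizes.values()) != len(self.assignments):
            raise ValidationError("cluster sizes do not sum to frame count")
        for cid, center in self.centers.items():
            if self.assignments.get(center) != cid:
                raise ValidationError(f"center {center} not a member of cluster {cid}")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _selection_indices(traj: Trajectory,
                       selection: Literal["heavy", "ca"]) -> np.ndarray:
    idx = []
    for i, (_res, atom) in enumerate(traj.topology.atoms()):
        if selection == "heavy" and not atom.is_hydrogen:
            idx.append(i)
        elif selection == "ca" and atom.name == "CA":
            idx.append(i)
    if len(idx) < 3:
        raise ValidationError("selection resolves to fewer than 3 atoms")
    return np.array(idx)


def pairwise_rmsd_matrix(traj: Trajectory,
                         selection: Literal["heavy", "ca"] = "heavy",
                         stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of per-pair Kabsch-fitted RMSDs (nm).

    Returns ``(matrix, frame_indices)`` where ``frame_indices`` maps
    matrix rows back to trajectory frames after striding.  The same atom
    selection is used for the fit and the measurement.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    sel = _selection_indices(traj, selection)
    frames = np.arange(0, traj.n_frames, stride)
    if frames.size < 2:
        raise ValidationError("need >= 2 frames after striding")
    coords = traj.frames[frames][:, sel, :]
    n = frames.size
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_superpose(coords[i], coords[j]).rmsd
    return mat, frames


def daura_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Neighbour-count clustering of an RMSD matrix at ``cutoff`` (nm).

    Ties on neighbour count break toward the lowest frame index, making
    the result deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"matrix must be square, got {matrix.shape}")
    if np.any(matrix < 0):
        raise ValidationError("matrix must be non-negative")
    if np.abs(matrix - matrix.T).max() > 1e-8:
        raise ValidationError("matrix is not symmetric")
    n = matrix.shape[0]
    neighbor = matrix <= cutoff
    np.fill_diagonal(neighbor, True)

    remaining = np.ones(n, dtype=bool)
    assignments: dict[int, int] = {}
    raw_clusters: list[tuple[int, list[int]]] = []
    while remaining.any():
        counts = (neighbor & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbor[center] & remaining)[0]
        raw_clusters.append((center, members.tolist()))
        remaining[members] = False
    order = sorted(range(len(raw_clusters)),
                   key=lambda k: (-len(raw_clusters[k][1]), raw_clusters[k][0]))
    centers: dict[int, int] = {}
    sizes: dict[int, int] = {}
    for cid, k in enumerate(order):
        center, members = raw_clusters[k]
        centers[cid] = center
        sizes[cid] = len(members)
        for m in members:
            assignments[m] = cid
    return ClusterResult(assignments=assignments, centers=centers,
                         cutoff=float(cutoff), sizes=sizes)


def representative_structure(traj: Trajectory, result: ClusterResult,
                             cluster_id: int,
                             frame_indices: np.ndarray | None = None) -> Structure:
    """Structure of a cluster's center frame (writable as PDB).

    ``frame_indices`` maps matrix rows to trajectory frames when the
    matrix was built with a stride.
    """
    if cluster_id not in result.centers:
        raise ChainLookupError(f"no cluster {cluster_id}")
    row = result.centers[cluster_id]
    frame = int(frame_indices[row]) if frame_indices is not None else row
    return traj.frame_structure(frame)
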