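"""Shared fixtures: tiny structures, reference oracles, narrative stats."""

import math

import numpy as np
import pytest

import thermoseg as ts
from thermoseg.structure import Atom, Residue, Structure


@pytest.fixture(autouse=True)
def _quiet_warnings():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_donor_acceptor_frame(da_dist, hda_angle_deg, donor_res=1, acceptor_res=5):
    """Two alanine-like residues with the acceptor's backbone O placed at a
    controlled distance/angle from the donor's backbone N.

    The H sits 0.1 nm from N, rotated ``hda_angle_deg`` off the N->O axis.
    """
    d = np.array([0.0, 0.0, 0.0])
    axis = np.array([1.0, 0.0, 0.0])
    acc = d + da_dist * axis
    theta = math.radians(hda_angle_deg)
    h = d + 0.1 * np.array([math.cos(theta), math.sin(theta), 0.0])
    res1 = Residue("ALA", donor_res, "A", [
        Atom("N", "N", d, 1),
        Atom("H", "H", h, 2),
        Atom("CA", "C", d + [0.0, -0.2, 0.0], 3),
        Atom("C", "C", d + [0.15, -0.3, 0.0], 4),
        Atom("O", "O", d + [0.15, -0.45, 0.0], 5),
    ])
    res2 = Residue("ALA", acceptor_res, "A", [
        Atom("N", "N", acc + [2.0, 0.0, 0.0], 6),
        Atom("H", "H", acc + [2.1, 0.0, 0.0], 7),
        Atom("CA", "C", acc + [2.0, -0.2, 0.0], 8),
        Atom("C", "C", acc + [0.1, -0.1, 0.0], 9),
        Atom("O", "O", acc, 10),
    ])
    return Structure({"A": [res1, res2]})


def brute_force_hbonds(topology, frame_coords, damap, criteria):
    """Exhaustive O(donors x acceptors) reference detector.

    Pure-python double loop with its own geometry, independent of the
    production detector's vectorized path.
    """
    index = topology.atom_index()
    events = set()
    for res_key, heavy, hydrogens in damap.donors:
        di = index.get((res_key[0], res_key[1], heavy))
        if di is None:
            continue
        d = frame_coords[di]
        for acc_key, acc_atom in damap.acceptors:
            ai = index.get((acc_key[0], acc_key[1], acc_atom))
            if ai is None or ai == di:
                continue
            if res_key == acc_key:
                continue
            if (res_key[0] == acc_key[0] and heavy == "N" and acc_atom == "O"
                    and res_key[1] == acc_key[1] + 1):
                continue
            a = frame_coords[ai]
            dist = math.dist(d, a)
            if dist > criteria.max_da_dist or dist == 0:
                continue
            for h_name in hydrogens:
                hi = index.get((res_key[0], res_key[1], h_name))
                if hi is None:
                    continue
                hvec = frame_coords[hi] - d
                avec = a - d
                nh = math.sqrt(sum(x * x for x in hvec))
                if nh == 0:
                    continue
                cosang = float(np.dot(hvec, avec)) / (nh * dist)
                cosang = max(-1.0, min(1.0, cosang))
                if math.degrees(math.acos(cosang)) <= criteria.max_hda_angle + 1e-9:
                    events.add(((res_key, heavy), h_name, (acc_key, acc_atom)))
    return events


def needleman_wunsch_score(a, b, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Gotoh affine-gap global alignment score (end gaps penalized).

    Independent dynamic-programming oracle; ``gap_open`` is the score of a
    gap's first residue, matching the aligner convention under test.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def alignment_score(aln, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Score an AlignmentPair column by column under the same convention."""
    score = 0.0
    prev_gap = None  # which side was gapped in the previous column
    for ca, cb in zip(aln.seq_a, aln.seq_b):
        if ca == "-" or cb == "-":
            side = "a" if ca == "-" else "b"
            score += gap_extend if prev_gap == side else gap_open
            prev_gap = side
        else:
            score += matrix[ca, cb]
            prev_gap = None
    return score


@pytest.fixture(scope="session")
def narrative_stats():
    from thermoseg import datasets
    return datasets.load_hbond_stats()


@pytest.fixture(scope="session")
def all_18_sites():
    from thermoseg import datasets
    positions = []
    for start, a, b in datasets.SEGMENTS:
        for k, (ra, rb) in enumerate(zip(a, b)):
            if ra != rb:
                positions.append(start + k)
    return positions
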