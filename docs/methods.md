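# Methods

This note documents the models and procedures thermoseg implements, the
defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer should know about.

## Units and containers

All coordinates are nanometres internally; PDB I/O converts Å↔nm at the
boundary.  Structures are chain → residue → atom trees keyed by PDB
author numbering (1-based, segments inclusive of both endpoints);
trajectories are `(n_frames, n_atoms, 3)` arrays over a fixed topology
with a frame spacing in ps.  Multi-model PDB is the native trajectory
carrier (one MODEL per frame); parsing and writing go through biotite,
which also resolves alternate locations by occupancy (ties fall to
biotite's first-record order).  Crystallographic waters and HETATM
records are stripped by default, both toggleable.

## Round 1: divergent segments

Sequences extracted from the two structures are aligned globally with
Bio.Align's PairwiseAligner (BLOSUM62, gap open −10, gap extend −0.5;
affine end gaps penalized).  The aligner's first reported alignment is
used; tests assert its score equals an independent Gotoh
dynamic-programming oracle rather than pinning a particular tie branch.

All aligned, gap-free columns with a Cα on both sides enter a single
Kabsch superposition (SVD with the reflection branch corrected to
det = +1; collinear point sets are rejected).  No outlier rejection or
iterative trimming is applied by default — the deviation profile is the
per-column Cα–Cα distance after one global fit, which is the simplest
defensible reading of "superimpose, then measure".  Segments are maximal
runs of ≥ `min_len` (default 6, the shortest segment of the phytase
study) consecutive gap-free columns with deviation > `threshold`
(default 0.3 nm); a gap column breaks a run because a segment requires
one-to-one residue pairing.  Substitutions are the differing residues
inside called segments; mainchain deviation uses Cα only, not N/C/O.

## Round 2: hydrogen-bond occupancy and selection

A bond is a (donor heavy atom, hydrogen, acceptor) triple with
donor–acceptor distance ≤ 0.35 nm and hydrogen–donor–acceptor angle
≤ 30° (vertex at the donor; 0° = linear; both criteria inclusive).
Donors and acceptors come from amino-acid templates restricted to N and
O (sulfur behind a flag): backbone amide N donates (except proline),
carbonyl O accepts; hydroxyls donate and accept; Asn/Gln amides donate
via N and accept via O; Lys/Arg/Trp nitrogens donate; carboxylates
accept.  Histidine ring nitrogens accept by default and donate only
under an explicit per-residue protonation override, because protonation
assignment is an input here, not a prediction.  With hydrogens present,
attachment is confirmed geometrically (D–H < 0.12 nm) with template
names as fallback; a donor with no resolvable hydrogen is dropped with a
warning.  Exclusions: intra-residue pairs, and the amide N(i+1) /
carbonyl O(i) pair across a peptide bond (1–3 neighbours).  No periodic
boundary handling is assumed — frames are expected whole.

Per residue pair, **occupancy** counts a frame once if any triple bonds
(the union over the pair's triples), while **mean_count** averages the
number of distinct simultaneous triples; this is why mean counts can
exceed 1 for bidentate contacts while occupancies cannot.  Uncertainty
is the standard error of block means over consecutive 10-ns blocks
(trailing partial block dropped; < 2 full blocks yields NaN with a
warning in the aggregate path, an error in the standalone routine).
Block SE depends on frame order; occupancy and mean count do not.

The selection rule formalizes otherwise qualitative judgements.  At the
stress temperature (70 °C by default; the working temperature is
reported as context only):

* `new_bond` — some pair has wild-type occupancy < `eps_absent` (0.05)
  and mutant occupancy ≥ `theta_new` (0.15);
* `strengthened` — some pair gains ≥ `delta_gain` (0.10) occupancy, or
  its mean count grows ≥ `ratio_gain` (1.5)-fold to ≥ `min_count` (0.5);
* `weakened` — every informative pair loses occupancy;
* `unchanged` — anything else, including sites with no informative pair.

Sites classified `new_bond` or `strengthened` are selected.  A pair
joining two mutated sites credits both.  The defaults were chosen so
that every comparison in the bundled AnP/AnP-M1 table resolves the way
the study's narrative resolves it (a 25 % newly appearing bond selects;
a 0.88 → 0.78 mean-count drop rejects); they are all configurable, and
the nine-site outcome under defaults is pinned by a test.  Decreasing
`delta_gain` or `theta_new` can only grow the selected set.

The bundled occupancy table transcribes the printed WT/M1 values where
numbers were printed and encodes bar-chart-only comparisons as plausible
values with `provenance=figure`; those rows were additionally chosen to
be realizable by the trajectory generator (mean count ≤ 2× occupancy).

## Clustering

Pairwise RMSD uses the same heavy-atom selection for the Kabsch fit and
the measurement.  Clustering is the greedy neighbour-count (Daura)
scheme: the frame with most neighbours within the cutoff (default
0.1 nm, the conventional default of the tool family; snapshot striding
honors a 10-ps interval when the spacing is known) seeds a cluster,
members are removed, and the scan repeats; ties break to the lowest
frame index, cluster ids are ordered by descending size.  Note that the
greedy scheme does **not** guarantee a non-increasing cluster count as
the cutoff grows on arbitrary matrices — a larger first cluster can
strand frames that previously clustered together — so the monotonicity
property is asserted on separated-basin geometries, where it holds.

## Kinetics

v = V_max·S/(K_m+S) is fitted by nonlinear least squares in
log-parameter space (positivity without constraints), initialized at
V_max⁰ = max rate and K_m⁰ = the substrate concentration at half-max by
linear interpolation; scipy's Levenberg–Marquardt refines to tight
tolerances.  Standard errors are asymptotic (Jacobian) estimates
delta-mapped back to the natural scale; both fit SEs and replicate SDs
are reported where replicates exist, since either convention may be
wanted.  Degenerate inputs (all-zero rates) return `converged=False`
with a diagnostic rather than raising.  k_cat is accepted as direct
input; converting V_max (μmol·min⁻¹·mg⁻¹) requires the molar mass,
which is optional.  Reporting rounds K_m/V_max/k_cat and k_cat/K_m to
one decimal.

## Synthetic data: what it does and does not emulate

Structure pairs are idealized helical backbones (0.15 nm rise, 100°
turn, template N/C/O/CB placement) with planted rigid per-segment
displacements in a seeded random direction plus isotropic Gaussian
background noise; sequences are identical so alignment is trivially the
identity.  Because the global fit includes displaced residues, planted
segments must be short relative to the chain for exact recovery — the
defaults keep them so.

Hydrogen-bond trajectories place an Asn-like residue per scheduled
participant (donor slots N–H and ND2–HD21; pure acceptor slots O and
OD1) on a widely spaced grid, then move each pair's acceptor atom to
0.30 nm/0° in exactly `round(occupancy × n_frames)` frames of a seeded
permutation schedule and to 0.45 nm otherwise.  Occupancy targets are
therefore *exact*, not sampled; a Bernoulli mode exists behind a flag
for testing block errors.  Mean counts above occupancy add a second
simultaneous triple on a subset schedule, capping mean count at twice
the occupancy; infeasible schedules raise.  Acceptor atoms never donate
(the reason for the Asn-like template), so no reverse bonds appear.
Temperatures and variants are labels only: no energetics, solvent or
dynamics are simulated, which is precisely what these fixtures do *not*
show about real trajectories — passing tests demonstrate the analysis
chain, not force-field behaviour.

Kinetics data are exact Michaelis–Menten curves at 12 concentrations
spanning 50–2500 μM (the assayed range, linearly spaced) with optional
multiplicative Gaussian noise; negative draws truncate at zero with a
warning.  All generators are seed-deterministic.

## Problem sizes

The shipped tests and the acceptance script run at desk scale:
generated trajectories of 200–2000 frames (occupancy schedules are
exact at any length), structures of 20–200 residues, 6–20-frame
clustering fixtures, and 50–200-seed noise studies.  These sizes were
chosen because the quantities under test are either exact by
construction or already stable there.

## Known limitations

mmCIF is not parsed; no water-mediated bridges, salt-bridge scoring or
bond-lifetime analysis; no multiple-structure or sequence-free
structural alignment; no ΔΔG prediction; the AfP crystal structure is
not bundled (no accession is available), so segment calling on the real
structure pair requires user-supplied files.
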