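"""Bundled reference inputs for the phytase design worked example.

The package ships the printed inputs of the AnP (*Aspergillus niger*
PhyA) / AfP (*A. fumigatus*) thermostabilization study so the full design
workflow runs with no external files: the three divergent segment
sequence pairs, the Michaelis–Menten parameter table of the wild type and
the two designed variants, the residual-activity summary, and a curated
hydrogen-bond occupancy table for wild type vs the 18-substitution
variant at 50 °C and 70 °C.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .hbonds import PairKey, PairStats, make_pair_key
from .synthetic import PairSchedule, TrajectorySpec

#: Divergent segment sequence pairs: (start, target/AnP, homolog/AfP).
SEGMENTS = (
    (35, "ANESVISP", "EDELSVSS"),
    (163, "RAQPGQ", "GATNRA"),
    (248, "TSTVDTK", "RTSDASQ"),
)

#: Michaelis–Menten parameters of the three enzymes:
#: Km (μM), Vmax (μmol/min/mg), kcat (/s).
KINETICS_TABLE = {
    "AnP": {"Km": 289.8, "Vmax": 5954.2, "kcat": 4885.4},
    "AnP-M1": {"Km": 116.5, "Vmax": 3117.1, "kcat": 2557.6},
    "AnP-M2": {"Km": 135.2, "Vmax": 2484.4, "kcat": 2042.6},
}

#: Residual activity (%) after 1 h incubation, by enzyme and temperature.
RESIDUAL_ACTIVITY = {
    ("AnP", 70): 31.0, ("AnP-M1", 70): 51.0, ("AnP-M2", 70): 66.0,
    ("AnP", 80): 21.0, ("AnP-M1", 80): 41.0, ("AnP-M2", 80): 58.0,
}

_WORK_TEMP = "50C"
_STRESS_TEMP = "70C"


def load_hbond_stats_frame() -> pd.DataFrame:
    """The curated AnP/AnP-M1 occupancy table as a DataFrame."""
    path = resources.files("thermoseg.data") / "anp_m1_hbond_stats.tsv"
    with resources.as_file(path) as fp:
        return pd.read_csv(fp, sep="\t", comment="#")


def load_hbond_stats(chain_id: str = "A",
                     ) -> tuple[dict[str, dict[PairKey, PairStats]],
                                dict[str, dict[PairKey, PairStats]]]:
    """Curated stats as ``(wt, mut)`` maps: temperature -> {pair -> PairStats}."""
    frame = load_hbond_stats_frame()
    wt: dict[str, dict[PairKey, PairStats]] = {_WORK_TEMP: {}, _STRESS_TEMP: {}}
    mut: dict[str, dict[PairKey, PairStats]] = {_WORK_TEMP: {}, _STRESS_TEMP: {}}
    for row in frame.itertuples(index=False):
        key = make_pair_key((chain_id, int(row.res_a)), (chain_id, int(row.res_b)))
        target = wt if row.variant == "wt" else mut
        target[row.temperature][key] = PairStats(
            pair=key,
            variant="AnP" if row.variant == "wt" else "AnP-M1",
            temperature=row.temperature,
            n_frames=0,
            occupancy=float(row.occupancy),
            mean_count=float(row.mean_count),
            block_se=float("nan"),
        )
    return wt, mut


def _orient_schedule(rows) -> list[PairSchedule]:
    """Assign donor/acceptor sides so no residue exceeds its two donor and
    two acceptor atom slots (a pair whose mean count exceeds its occupancy
    consumes two slots on each side)."""
    donor_used: dict[int, int] = {}
    acc_used: dict[int, int] = {}
    schedule = []
    for r in rows:
        a, b = int(r.res_a), int(r.res_b)
        occ, mc = float(r.occupancy), float(r.mean_count)
        slots = 2 if mc > occ + 1e-12 else 1
        placed = False
        for donor, acceptor in ((b, a), (a, b)):
            if donor_used.get(donor, 0) + slots <= 2 and \
                    acc_used.get(acceptor, 0) + slots <= 2:
                donor_used[donor] = donor_used.get(donor, 0) + slots
                acc_used[acceptor] = acc_used.get(acceptor, 0) + slots
                schedule.append(PairSchedule(donor_res=donor, acceptor_res=acceptor,
                                             occupancy=occ, mean_count=mc))
                placed = True
                break
        if not placed:
            raise ValueError(f"pair {a}-{b}: donor/acceptor atom slots exhausted")
    return schedule


def narrative_trajectory_specs(n_frames: int = 2000, seed: int = 0,
                               ) -> dict[tuple[str, str], TrajectorySpec]:
    """Trajectory specs realizing the curated table, one spec per
    (variant, temperature) condition."""
    frame = load_hbond_stats_frame()
    specs: dict[tuple[str, str], TrajectorySpec] = {}
    for i, ((variant, temp), grp) in enumerate(
            frame.groupby(["variant", "temperature"], sort=True)):
        schedule = _orient_schedule(grp.itertuples(index=False))
        specs[(variant, temp)] = TrajectorySpec(
            variant="AnP" if variant == "wt" else "AnP-M1",
            temperature=temp, n_frames=n_frames,
            pair_schedule=schedule, seed=seed + i,
        )
    return specs
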