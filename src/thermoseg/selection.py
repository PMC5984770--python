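"""Second-round mutation selection from hydrogen-bond occupancy changes.

Given per-pair occupancy statistics for the wild type and a multi-site
mutant at a working temperature and a stress temperature, each mutated
site is classified by what its hydrogen-bond network does at the stress
temperature:

* ``new_bond`` — a pair essentially absent in the wild type (occupancy
  below ``eps_absent``) appears in the mutant at or above ``theta_new``;
* ``strengthened`` — a pair's occupancy gain reaches ``delta_gain``, or
  its mean simultaneous-bond count grows by at least ``ratio_gain``-fold
  to at least ``min_count``;
* ``weakened`` — every informative pair lost occupancy;
* ``unchanged`` — anything else (including sites with no informative pair).

Sites classified ``new_bond`` or ``strengthened`` are selected for the
refined design.  A pair connecting two mutated sites credits both.  The
thresholds formalize otherwise qualitative judgements ("rarely observed",
"4-fold greater") and are all configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .compare import SubstitutionSet
from .errors import ValidationError
from .hbonds import PairKey, PairStats, make_pair_key
from .structure import ResKey


@dataclass
class SelectionThresholds:
    eps_absent: float = 0.05   # occupancy below which a WT pair counts as absent
    theta_new: float = 0.15    # minimum mutant occupancy for a "new" pair
    delta_gain: float = 0.10   # minimum occupancy gain at the stress temperature
    ratio_gain: float = 1.5    # minimum mean-count fold gain
    min_count: float = 0.5     # minimum mutant mean count for count-based calls

    def __post_init__(self) -> None:
        if not (0 < self.eps_absent < self.theta_new <= 1):
            raise ValidationError("need 0 < eps_absent < theta_new <= 1")
        if not self.delta_gain > 0:
            raise ValidationError("delta_gain must be > 0")
        if not self.ratio_gain > 1:
            raise ValidationError("ratio_gain must be > 1")


@dataclass
class SideStats:
    """Occupancy and mean count of one variant at one temperature (zeros
    when the pair was never observed for that variant)."""

    occupancy: float = 0.0
    mean_count: float = 0.0


@dataclass
class OccupancyComparison:
    """WT-vs-mutant record for one (mutated site, residue pair)."""

    site: int
    pair: PairKey
    wt_work: SideStats
    wt_stress: SideStats
    mut_work: SideStats
    mut_stress: SideStats

    def __post_init__(self) -> None:
        if self.site not in {self.pair[0][1], self.pair[1][1]}:
            raise ValidationError(f"site {self.site} not a member of pair {self.pair}")

    @property
    def informative(self) -> bool:
        return (self.wt_stress.occupancy > 0 or self.mut_stress.occupancy > 0
                or self.wt_stress.mean_count > 0 or self.mut_stress.mean_count > 0)


@dataclass
class CandidateSite:
    position: int
    classification: str  # new_bond | strengthened | unchanged | weakened
    evidence: list[str] = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return self.classification in ("new_bond", "strengthened")


def _side(stats: Mapping[PairKey, PairStats] | None, key: PairKey) -> SideStats:
    if stats is None:
        return SideStats()
    rec = stats.get(key)
    if rec is None:
        return SideStats()
    return SideStats(occupancy=rec.occupancy, mean_count=rec.mean_count)


def compare_pairs(wt: Mapping[str, Mapping[PairKey, PairStats]],
                  mut: Mapping[str, Mapping[PairKey, PairStats]],
                  sites: SubstitutionSet | Iterable[int],
                  work_temp: str, stress_temp: str,
                  chain_id: str = "A") -> list[OccupancyComparison]:
    """Build per-(site, pair) comparisons from WT and mutant stats.

    ``wt``/``mut`` map temperature label -> {pair -> PairStats}.  A pair
    enters when either variant shows nonzero occupancy at either
    temperature; the missing counterpart is imputed as zeros.  Sites are
    substitution positions; a pair involving two mutated positions yields
    one comparison per site.
    """
    for name, stats in (("wt", wt), ("mut", mut)):
        for temp in (work_temp, stress_temp):
            if temp not in stats:
                raise ValidationError(f"{name} stats missing temperature {temp!r}")
    positions = set(sites.positions if isinstance(sites, SubstitutionSet) else sites)
    all_pairs: set[PairKey] = set()
    for stats in (wt, mut):
        for temp in (work_temp, stress_temp):
            all_pairs.update(stats[temp].keys())

    comparisons: list[OccupancyComparison] = []
    for key in sorted(all_pairs):
        member_sites = [rk[1] for rk in key if rk[1] in positions]
        if not member_sites:
            continue
        record = {
            "wt_work": _side(wt.get(work_temp), key),
            "wt_stress": _side(wt.get(stress_temp), key),
            "mut_work": _side(mut.get(work_temp), key),
            "mut_stress": _side(mut.get(stress_temp), key),
        }
        if not any(s.occupancy > 0 or s.mean_count > 0 for s in record.values()):
            continue
        for site in member_sites:
            comparisons.append(OccupancyComparison(site=site, pair=key, **record))
    return comparisons


def classify_site(comparisons: list[OccupancyComparison],
                  thresholds: SelectionThresholds = SelectionThresholds(),
                  ) -> CandidateSite:
    """Classify one mutated site from all its pair comparisons.

    Rules fire in priority order new_bond > strengthened > weakened, all
    evaluated at the stress temperature; the result does not depend on the
    order of the comparisons.
    """
    if not comparisons:
        raise ValidationError("need >= 1 comparison")
    site = comparisons[0].site
    if any(c.site != site for c in comparisons):
        raise ValidationError("comparisons span multiple sites")
    thr = thresholds
    evidence: list[str] = []

    def pair_label(c: OccupancyComparison) -> str:
        return f"{c.pair[0][1]}-{c.pair[1][1]}"

    new_hits = [
        c for c in comparisons
        if c.wt_stress.occupancy < thr.eps_absent
        and c.mut_stress.occupancy >= thr.theta_new
    ]
    if new_hits:
        for c in sorted(new_hits, key=pair_label):
            evidence.append(
                f"new_bond {pair_label(c)}: wt {c.wt_stress.occupancy:.2f} -> "
                f"mut {c.mut_stress.occupancy:.2f}"
            )
        return CandidateSite(site, "new_bond", evidence)

    strengthened_hits = []
    for c in comparisons:
        occ_gain = c.mut_stress.occupancy - c.wt_stress.occupancy
        count_ok = (
            c.mut_stress.mean_count >= thr.ratio_gain * c.wt_stress.mean_count
            and c.mut_stress.mean_count >= thr.min_count
        )
        if occ_gain >= thr.delta_gain:
            strengthened_hits.append(
                (c, f"strengthened {pair_label(c)}: occupancy +{occ_gain:.2f}")
            )
        elif count_ok:
            strengthened_hits.append(
                (c, f"strengthened {pair_label(c)}: mean count "
                    f"{c.wt_stress.mean_count:.2f} -> {c.mut_stress.mean_count:.2f}")
            )
    if strengthened_hits:
        for _, msg in sorted(strengthened_hits, key=lambda t: pair_label(t[0])):
            evidence.append(msg)
        return CandidateSite(site, "strengthened", evidence)

    informative = [c for c in comparisons if c.informative]
    if informative and all(
        c.mut_stress.occupancy < c.wt_stress.occupancy for c in informative
    ):
        for c in sorted(informative, key=pair_label):
            evidence.append(
                f"weakened {pair_label(c)}: wt {c.wt_stress.occupancy:.2f} -> "
                f"mut {c.mut_stress.occupancy:.2f}"
            )
        return CandidateSite(site, "weakened", evidence)
    return CandidateSite(site, "unchanged", ["no rule fired"])


def select_candidates(comparisons: list[OccupancyComparison],
                      thresholds: SelectionThresholds = SelectionThresholds(),
                      sites: SubstitutionSet | Iterable[int] | None = None,
                      ) -> tuple[list[CandidateSite], tuple[int, ...]]:
    """Classify every mutated site; return candidates and the selected set.

    Sites with no comparison are classified ``unchanged`` with a warning.
    Output is ordered by position, which is segment order for segment-wise
    designs.
    """
    by_site: dict[int, list[OccupancyComparison]] = {}
    for c in comparisons:
        by_site.setdefault(c.site, []).append(c)
    wanted = None
    if sites is not None:
        wanted = sorted(set(
            sites.positions if isinstance(sites, SubstitutionSet) else sites
        ))
        for pos in wanted:
            if pos not in by_site:
                warnings.warn(f"site {pos} has no comparisons; classified unchanged")
    positions = wanted if wanted is not None else sorted(by_site)
    candidates = []
    for pos in positions:
        if pos in by_site:
            candidates.append(classify_site(by_site[pos], thresholds))
        else:
            candidates.append(CandidateSite(pos, "unchanged", ["no comparisons"]))
    selected = tuple(c.position for c in candidates if c.selected)
    return candidates, selected
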