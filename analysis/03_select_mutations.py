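#!/usr/bin/env python
"""Round-2 design: apply the selection rule to WT vs mutant occupancies.

Classifies each of the 18 round-1 sites from the curated AnP/AnP-M1
occupancy table at the 70C stress temperature and writes the refined
selection.  Sites whose hydrogen-bond networks appear or strengthen in
the mutant are kept; weakened or unchanged sites are dropped.

Writes results/round2_candidates.tsv.
"""

import os
import warnings

import pandas as pd

import thermoseg as ts
from thermoseg import datasets

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    sites = []
    for start, a, b in datasets.SEGMENTS:
        sites += [start + k for k, (x, y) in enumerate(zip(a, b)) if x != y]

    wt, mut = datasets.load_hbond_stats()
    comps = ts.compare_pairs(wt, mut, sites, "50C", "70C")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates, selected = ts.select_candidates(
            comps, ts.SelectionThresholds(), sites=sites)

    frame = pd.DataFrame([{
        "position": c.position,
        "classification": c.classification,
        "selected": c.selected,
        "evidence": "; ".join(c.evidence),
    } for c in candidates])
    frame.to_csv(os.path.join(OUT, "round2_candidates.tsv"),
                 sep="\t", index=False)
    print(f"{len(selected)} of {len(sites)} sites selected: {list(selected)}")
    counts = frame["classification"].value_counts().to_dict()
    print(f"classification breakdown: {counts}")


if __name__ == "__main__":
    main()
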