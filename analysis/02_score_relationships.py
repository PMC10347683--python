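#!/usr/bin/env python
"""Stage 2: drug-target/disease-effector relationship scoring.

Takes the interactome and characterizations written by stage 1, embeds the
drug targets into the network (as a degree-stratified random placement,
since the synthetic universe has no real gene symbols), and scores the
proximity of the target set to each comorbidity's effector set against a
degree-matched permutation null. Scores are mapped to the 0-100 scale whose
bands correspond to empirical p-value thresholds (>=92 <-> p<0.01,
77-92 <-> p<0.05, 37-77 <-> p<0.25, <37 <-> p>=0.25).

Writes: results/analysis/relationship_scores.tsv.
"""

from pathlib import Path

import numpy as np

from comornet.characterization import load_characterization
from comornet.interactome import load_edge_dump
from comornet.scoring import empirical_score, proximity_statistic, write_score_report

OUT = Path("results/analysis")
SEED = 2026


def main() -> None:
    net = load_edge_dump(OUT / "interactome.tsv")
    base = load_characterization(OUT / "disease_0.tsv", "disease_0")
    rng = np.random.default_rng(SEED + 1)

    # drug targets as a placement inside the base disease's effectors,
    # mirroring a drug designed against the base disorder
    targets = set(rng.choice(sorted(base.genes), size=7, replace=False))
    rows = []
    for i in range(1, 6):
        disease = load_characterization(OUT / f"disease_{i}.tsv", f"disease_{i}")
        stat = proximity_statistic(targets, disease.genes, net)
        rel = empirical_score(stat, targets, disease.genes, net, n_null=499, seed=SEED + i)
        rows.append(("vLDX-like", disease.disease_id, rel))
        print(f"{disease.disease_id}: proximity={rel.raw_stat:.2f} "
              f"p={rel.empirical_p:.3g} score={rel.score:.0f} ({rel.band})")
    write_score_report(rows, OUT / "relationship_scores.tsv")
    print(f"wrote {OUT / 'relationship_scores.tsv'}")


if __name__ == "__main__":
    main()
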