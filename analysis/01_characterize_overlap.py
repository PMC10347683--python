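#!/usr/bin/env python
"""Stage 1: molecular characterizations and effector-overlap statistics.

Loads the packaged drug target table, generates a DS2-style universe of six
disease characterizations (one base disorder plus five comorbidities)
embedded in a synthetic scale-free interactome, and reports how much of the
base disease's effector set is shared with, or directly connected to, the
comorbidities.

Writes: results/analysis/overlap.json and per-disease characterization TSVs.
"""

import json
from pathlib import Path

from comornet.characterization import (
    connected_overlap,
    effector_overlap,
    load_drug_definition,
    write_characterization,
)
from comornet.interactome import write_edge_dump
from comornet.synthetic import SynthSpec, fixture_path, synth_characterizations, synth_interactome

OUT = Path("results/analysis")
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    drug = load_drug_definition(fixture_path("ldx_targets.tsv"), "vLDX")
    print(f"drug {drug.drug_id}: {len(drug.targets)} targets "
          f"({sum(v > 0 for v in drug.targets.values())} activated, "
          f"{sum(v < 0 for v in drug.targets.values())} inhibited)")

    spec = SynthSpec(
        n_nodes=1000, attachment=3, n_diseases=6, effectors_per_disease=60,
        overlap_with_base=(0.34, 0.20, 0.15, 0.12, 0.08),
        base_union_overlap=0.53, seed=SEED,
    )
    net = synth_interactome(spec)
    diseases = synth_characterizations(spec, net)
    write_edge_dump(net, OUT / "interactome.tsv")
    for disease in diseases:
        write_characterization(disease, OUT / f"{disease.disease_id}.tsv")

    base, others = diseases[0], diseases[1:]
    report = effector_overlap(base, others)
    connected = connected_overlap(base, others, net)
    print(f"base disease shares {report.aggregate:.1f}% of its effectors with >=1 comorbidity")
    print(f"per-comorbidity sharing: "
          + ", ".join(f"{d}={v:.1f}%" for d, v in sorted(report.per_pair.items())))
    print(f"shared or directly connected: {connected:.1f}%")

    payload = {
        "seed": SEED,
        "aggregate_pct": report.aggregate,
        "per_pair_pct": dict(report.per_pair),
        "connected_pct": connected,
        "drug_targets": dict(drug.targets),
    }
    (OUT / "overlap.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"wrote {OUT / 'overlap.json'}")


if __name__ == "__main__":
    main()
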