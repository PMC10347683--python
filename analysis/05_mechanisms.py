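#!/usr/bin/env python
"""Stage 5: mechanism-of-action outcomes on a compact virtual study.

Runs the full per-patient chain on a small synthetic universe: cohorts ->
PBPK brain exposure -> Emax drug stimulus -> per-patient sampled model ->
protein activities -> reverted-effector consensus, tSignal and <=3-edge
mechanism paths. Also tallies the packaged published reverted-protein
tables through the same population bookkeeping.

Writes: results/analysis/moa.json and reverted_*.tsv.
"""

import json
from pathlib import Path

import numpy as np

from comornet.characterization import DrugDefinition
from comornet.moa import (
    consensus_reverted,
    extract_mechanism_paths,
    load_reverted_table,
    summarize_reverted_table,
    write_moa_tables,
)
from comornet.netmodel import (
    PropagationEngine,
    TrainingRestriction,
    drug_stimulus,
    propagate,
    sample_solutions,
)
from comornet.pbpk import default_parameters, pbpk_simulate
from comornet.synthetic import (
    SynthSpec,
    fixture_path,
    synth_characterizations,
    synth_interactome,
    synth_restrictions,
)
from comornet.virtual_patients import adult_default_spec, generate_cohort, pediatric_default_spec

OUT = Path("results/analysis")
SEED = 2026
N_PATIENTS = 10  # per cohort; compact on purpose
DOSE_MG = 70.0
EC50 = 0.05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SynthSpec(
        n_nodes=150, attachment=2, n_diseases=2, effectors_per_disease=20,
        overlap_with_base=(0.2,), base_union_overlap=0.2, seed=SEED + 20,
    )
    net = synth_interactome(spec)
    engine = PropagationEngine(net)
    base, comorbidity = synth_characterizations(spec, net)
    rng = np.random.default_rng(SEED + 21)
    target_genes = sorted(rng.choice(sorted(base.genes), size=5, replace=False))
    drug = DrugDefinition(
        drug_id="synthetic_drug",
        targets={g: -base.sign_of(g) for g in target_genes},
    )
    truth = engine.random_weights(rng)
    restrictions = synth_restrictions(net, truth, 8, seed=SEED + 22, engine=engine)

    # drug-pathophysiology part of the training set: the drug stimulus is
    # expected to revert comorbidity effectors reachable within the
    # propagation depth of a target
    reachable = set()
    frontier = set(drug.targets)
    for _ in range(3):
        frontier = {n for g in frontier for n in net.neighbors(g)}
        reachable |= frontier
    efficacy_genes = sorted(comorbidity.genes & reachable)[:8]
    restrictions.append(
        TrainingRestriction(
            stimulus=dict(drug.targets),
            expected_response={g: -comorbidity.sign_of(g) for g in efficacy_genes},
            tag="drug_efficacy",
        )
    )

    params = default_parameters()
    cohort_acts = {}
    cohort_models = {}
    for label, cohort_spec in (
        ("adult", adult_default_spec(n=100, seed=SEED + 23)),
        ("pediatric", pediatric_default_spec(n=100, seed=SEED + 24)),
    ):
        patients = generate_cohort(cohort_spec)[:N_PATIENTS]
        activities, models = [], []
        for p_idx, patient in enumerate(patients):
            exposure = pbpk_simulate(patient, params, DOSE_MG)
            stim = drug_stimulus(drug, exposure.brain, ec50=EC50)
            solution = sample_solutions(
                net, restrictions, n_accept=1, seed=SEED + 1000 + p_idx,
                max_draws=100, engine=engine, patient_id=patient.id,
            )[0]
            models.append(solution)
            activities.append(
                propagate(net, solution.edge_weights, stim, engine=engine)
            )
        cohort_acts[label] = activities
        cohort_models[label] = models

    report = consensus_reverted(cohort_acts["adult"], cohort_acts["pediatric"], comorbidity)
    all_models = cohort_models["adult"] + cohort_models["pediatric"]
    all_acts = cohort_acts["adult"] + cohort_acts["pediatric"]
    paths = extract_mechanism_paths(all_models, all_acts, drug, comorbidity, net, frequency_min=1.0)
    paths_half = extract_mechanism_paths(all_models, all_acts, drug, comorbidity, net, frequency_min=0.5)
    write_moa_tables(report, comorbidity, OUT)
    print(f"reverted effectors: adult {report.counts['Adult']}, "
          f"pediatric {report.counts['Pediatric']}, both {report.counts['Both']} "
          f"of {len(comorbidity.effectors)}")
    print(f"tSignal: adult {report.tsignal['adult']:.3f}, "
          f"pediatric {report.tsignal['pediatric-adolescent']:.3f} "
          f"(negative = net reversion)")
    print(f"mechanism paths at 100% population frequency: {len(paths)} "
          f"(at >=50%: {len(paths_half)})")

    tables = {
        name: summarize_reverted_table(load_reverted_table(fixture_path(f"{name}_reverted.tsv")))
        for name in ("bed", "depression")
    }
    print(f"published-table bookkeeping: BED {tables['bed']['total']} reverted "
          f"({tables['bed']['adhd_effectors']} ADHD effectors); depression "
          f"{tables['depression']['adult']} adult / {tables['depression']['pediatric']} pediatric")

    payload = {
        "reverted_counts": report.counts,
        "tsignal": dict(report.tsignal),
        "n_paths": len(paths),
        "n_paths_at_half_frequency": len(paths_half),
        "paths": [list(p.nodes) for p in (paths or paths_half)[:20]],
        "published_tables": tables,
    }
    (OUT / "moa.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"wrote {OUT / 'moa.json'}")


if __name__ == "__main__":
    main()
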