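"""Configuration-driven end-to-end orchestration.

A single YAML config drives the seven stages: characterize -> overlap
statistics -> relationship scoring -> virtual cohorts -> PBPK exposure ->
network-model sampling -> mechanism-of-action outcomes. Every stage writes
its outputs under the configured output directory, and a versioned summary
JSON collects the machine-readable results (overlap fractions, score bands,
reverted counts per population, path counts). All randomness flows from
seeds named in the config, so identical configs produce identical
summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from comornet import characterization as chz
from comornet import interactome as ine
from comornet import moa as moa_mod
from comornet import netmodel as nm
from comornet import pbpk as pk
from comornet import scoring as sc
from comornet import synthetic as syn
from comornet import virtual_patients as vp

SUMMARY_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Parsed pipeline configuration; see ``load_config`` for the YAML shape."""

    run_id: str
    seed: int
    outdir: Path
    drug_id: str
    drug_path: Path | None
    diseases: tuple[tuple[str, Path | None], ...]  # (disease_id, path); None -> synthetic
    base_disease: str
    interactome_tables: Mapping[str, Path] | None
    synth: syn.SynthSpec | None
    n_null: int
    cohort_n: int
    cohort_min_n: int
    dose_mg: float
    ec50: float
    n_steps: int
    accuracy_min: float
    max_draws: int
    n_restrictions: int
    restrictions_path: Path | None
    moa_threshold: float
    activation_min: float
    frequency_min: float
    reverted_tables: Mapping[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.moa_threshold < 1) or not (0 < self.activation_min < 1):
            raise ValueError("MoA thresholds must be in (0, 1)")
        if not (0 < self.frequency_min <= 1):
            raise ValueError("frequency_min must be in (0, 1]")
        if self.interactome_tables is None and self.synth is None:
            raise ValueError("config needs either interactome edge tables or a synthetic spec")


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Parse a YAML run configuration; referenced files must exist."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    root = path.parent

    def resolve(p: str | None) -> Path | None:
        if p is None:
            return None
        candidate = Path(p)
        full = candidate if candidate.is_absolute() else root / candidate
        if not full.exists():
            raise FileNotFoundError(f"config references missing file: {full}")
        return full

    synth_cfg = raw.get("synthetic")
    synth = syn.SynthSpec(**synth_cfg) if synth_cfg else None
    tables_cfg = raw.get("interactome", {}).get("edge_tables")
    tables = {tag: resolve(p) for tag, p in tables_cfg.items()} if tables_cfg else None
    diseases = tuple(
        (d["id"], resolve(d.get("path"))) for d in raw.get("diseases", [])
    )
    cohorts = raw.get("cohorts", {})
    netmodel = raw.get("netmodel", {})
    moa_cfg = raw.get("moa", {})
    return RunConfig(
        run_id=str(raw.get("run_id", path.stem)),
        seed=int(seed_override if seed_override is not None else raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "results") ) / str(raw.get("run_id", path.stem)),
        drug_id=str(raw.get("drug", {}).get("id", "drug")),
        drug_path=resolve(raw.get("drug", {}).get("path")),
        diseases=diseases,
        base_disease=str(raw.get("base_disease", diseases[0][0] if diseases else "disease_0")),
        interactome_tables=tables,
        synth=synth,
        n_null=int(raw.get("scoring", {}).get("n_null", 199)),
        cohort_n=int(cohorts.get("n", 100)),
        cohort_min_n=int(cohorts.get("min_n", vp.MIN_COHORT_SIZE)),
        dose_mg=float(cohorts.get("dose_mg", 70.0)),
        ec50=float(cohorts.get("ec50", 0.05)),
        n_steps=int(netmodel.get("n_steps", nm.DEFAULT_N_STEPS)),
        accuracy_min=float(netmodel.get("accuracy_min", nm.DEFAULT_ACCURACY_MIN)),
        max_draws=int(netmodel.get("max_draws", 200)),
        n_restrictions=int(netmodel.get("n_restrictions", 8)),
        restrictions_path=resolve(netmodel.get("restrictions")),
        moa_threshold=float(moa_cfg.get("threshold", 0.5)),
        activation_min=float(moa_cfg.get("activation_min", 0.8)),
        frequency_min=float(moa_cfg.get("frequency_min", 1.0)),
        reverted_tables={k: resolve(p) for k, p in raw.get("reverted_tables", {}).items()},
    )


def _stage(summary: dict, name: str) -> dict:
    summary["stages"][name] = {}
    return summary["stages"][name]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the summary dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "run_id": config.run_id,
        "seed": config.seed,
        "stages": {},
    }

    # 1. characterization -----------------------------------------------------
    section = _stage(summary, "characterization")
    try:
        need_synth = config.synth is not None and (
            not config.diseases or any(p is None for _, p in config.diseases)
        )
        if not config.diseases and config.synth is None:
            raise ValueError("no diseases configured and no synthetic spec to generate them")
        if need_synth:
            net_for_synth = syn.synth_interactome(config.synth)
            synth_diseases = syn.synth_characterizations(config.synth, net_for_synth)
        else:
            net_for_synth = None
            synth_diseases = []
        diseases: dict[str, chz.DiseaseCharacterization] = {}
        if config.diseases:
            for i, (disease_id, path) in enumerate(config.diseases):
                if path is not None:
                    diseases[disease_id] = chz.load_characterization(path, disease_id)
                else:
                    d = synth_diseases[i]
                    diseases[disease_id] = chz.DiseaseCharacterization(
                        disease_id=disease_id, motives=d.motives, effectors=d.effectors
                    )
        else:
            diseases = {d.disease_id: d for d in synth_diseases}
        if config.drug_path is not None:
            drug = chz.load_drug_definition(config.drug_path, config.drug_id)
        else:
            # synthetic drug: signed targets drawn from the base disease's effectors
            rng = np.random.default_rng(config.seed + 11)
            base = diseases[config.base_disease]
            picks = sorted(rng.choice(sorted(base.genes), size=min(7, len(base.genes)), replace=False))
            drug = chz.DrugDefinition(
                drug_id=config.drug_id,
                targets={g: -base.sign_of(g) for g in picks},
            )
        for disease in diseases.values():
            chz.write_characterization(disease, outdir / f"characterization_{disease.disease_id}.tsv")
        section["diseases"] = {d: len(diseases[d].effectors) for d in diseases}
        section["drug_targets"] = len(drug.targets)
    except Exception as exc:
        raise PipelineError("characterization", str(exc)) from exc

    # 2. interactome + overlap ------------------------------------------------
    section = _stage(summary, "overlap")
    try:
        if config.interactome_tables is not None:
            net = ine.assemble_interactome(config.interactome_tables)
        else:
            net = net_for_synth if net_for_synth is not None else syn.synth_interactome(config.synth)
        ine.write_edge_dump(net, outdir / "interactome.tsv")
        base = diseases[config.base_disease]
        others = [d for d in diseases.values() if d.disease_id != config.base_disease]
        if others:
            report = chz.effector_overlap(base, others)
            section["aggregate_pct"] = report.aggregate
            section["per_pair_pct"] = dict(report.per_pair)
            section["connected_pct"] = chz.connected_overlap(base, others, net)
        else:
            section["aggregate_pct"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("overlap", str(exc)) from exc

    # 3. scoring --------------------------------------------------------------
    section = _stage(summary, "scoring")
    try:
        rows = []
        for disease in diseases.values():
            if disease.disease_id == config.base_disease:
                continue
            targets = set(drug.targets) & net.nodes
            if not targets:
                section[disease.disease_id] = None
                continue
            stat = sc.proximity_statistic(targets, disease.genes, net)
            rel = sc.empirical_score(
                stat, targets, disease.genes, net, n_null=config.n_null, seed=config.seed + 23
            )
            rows.append((drug.drug_id, disease.disease_id, rel))
            section[disease.disease_id] = {
                "raw_stat": rel.raw_stat,
                "empirical_p": rel.empirical_p,
                "score": rel.score,
                "band": rel.band,
            }
        sc.write_score_report(rows, outdir / "relationship_scores.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("scoring", str(exc)) from exc

    # 4. cohorts --------------------------------------------------------------
    section = _stage(summary, "cohorts")
    try:
        comorbidities = [d for d in diseases if d != config.base_disease] or [config.base_disease]
        cohorts: dict[tuple[str, str], list[vp.VirtualPatient]] = {}
        for c_idx, comorbidity in enumerate(comorbidities):
            adult = vp.adult_default_spec(
                n=config.cohort_n,
                min_n=config.cohort_min_n,
                seed=config.seed + 100 + c_idx,
                comorbidity=comorbidity,
            )
            pediatric = vp.pediatric_default_spec(
                n=config.cohort_n,
                min_n=config.cohort_min_n,
                seed=config.seed + 200 + c_idx,
                comorbidity=comorbidity,
            )
            cohorts[(comorbidity, "adult")] = vp.generate_cohort(adult)
            cohorts[(comorbidity, "pediatric-adolescent")] = vp.generate_cohort(pediatric)
        for (comorbidity, label), patients in cohorts.items():
            vp.write_cohort_csv(patients, outdir / f"cohort_{comorbidity}_{label}.csv")
        section["n_cohorts"] = len(cohorts)
        section["patients_per_cohort"] = config.cohort_n
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cohorts", str(exc)) from exc

    # 5. PBPK exposure --------------------------------------------------------
    section = _stage(summary, "pbpk")
    try:
        params = pk.default_parameters()
        section["oral_bioavailability"] = pk.oral_bioavailability(params)
        brain_cmax: dict[str, float] = {}
        exposures: dict[tuple[str, str], list[pk.ConcentrationCurve]] = {}
        for (comorbidity, label), patients in cohorts.items():
            curves = []
            for patient in patients:
                res = pk.pbpk_simulate(patient, params, config.dose_mg)
                curves.append(res.brain)
            exposures[(comorbidity, label)] = curves
            brain_cmax[f"{comorbidity}/{label}"] = float(np.mean([c.cmax for c in curves]))
        section["mean_brain_cmax_mg_per_l"] = brain_cmax
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("pbpk", str(exc)) from exc

    # 6. network-model sampling ----------------------------------------------
    section = _stage(summary, "netmodel")
    try:
        engine = nm.PropagationEngine(net)
        if config.restrictions_path is not None:
            restrictions = nm.load_restrictions(config.restrictions_path)
        else:
            rng = np.random.default_rng(config.seed + 31)
            truth = engine.random_weights(rng)
            restrictions = syn.synth_restrictions(
                net, truth, config.n_restrictions, seed=config.seed + 37, engine=engine
            )
        accuracies = []
        patient_models: dict[tuple[str, str], list[nm.NetworkModelSolution]] = {}
        for k_idx, ((comorbidity, label), patients) in enumerate(cohorts.items()):
            models = []
            for p_idx, patient in enumerate(patients):
                sol = nm.sample_solutions(
                    net,
                    restrictions,
                    n_accept=1,
                    accuracy_min=config.accuracy_min,
                    seed=config.seed + 1000 * (k_idx + 1) + p_idx,
                    max_draws=config.max_draws,
                    n_steps=config.n_steps,
                    patient_id=patient.id,
                    engine=engine,
                )[0]
                models.append(sol)
                accuracies.append(sol.accuracy)
            patient_models[(comorbidity, label)] = models
        section["n_restrictions"] = len(restrictions)
        section["min_accuracy"] = float(np.min(accuracies))
        section["mean_accuracy"] = float(np.mean(accuracies))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("netmodel", str(exc)) from exc

    # 7. MoA outcomes ---------------------------------------------------------
    section = _stage(summary, "moa")
    try:
        for comorbidity in comorbidities:
            disease = diseases[comorbidity]
            per_cohort_acts: dict[str, list[nm.ProteinActivity]] = {}
            for label in ("adult", "pediatric-adolescent"):
                models = patient_models[(comorbidity, label)]
                curves = exposures[(comorbidity, label)]
                acts = []
                for sol, curve in zip(models, curves):
                    stim = nm.drug_stimulus(drug, curve, ec50=config.ec50)
                    acts.append(
                        nm.propagate(net, sol.edge_weights, stim, n_steps=config.n_steps, engine=engine)
                    )
                per_cohort_acts[label] = acts
            report = moa_mod.consensus_reverted(
                per_cohort_acts["adult"],
                per_cohort_acts["pediatric-adolescent"],
                disease,
                threshold=config.moa_threshold,
            )
            paths = moa_mod.extract_mechanism_paths(
                patient_models[(comorbidity, "adult")] + patient_models[(comorbidity, "pediatric-adolescent")],
                per_cohort_acts["adult"] + per_cohort_acts["pediatric-adolescent"],
                drug,
                disease,
                net,
                activation_min=config.activation_min,
                frequency_min=config.frequency_min,
            )
            moa_mod.write_moa_tables(report, disease, outdir)
            section[comorbidity] = {
                "reverted_counts": report.counts,
                "tsignal": dict(report.tsignal),
                "n_paths": len(paths),
            }
        # optional published-style reverted tables through the same bookkeeping
        for name, table_path in config.reverted_tables.items():
            frame = moa_mod.load_reverted_table(table_path)
            section.setdefault("reverted_tables", {})[name] = moa_mod.summarize_reverted_table(frame)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("moa", str(exc)) from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
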