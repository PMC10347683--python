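"""Mechanism-of-action outcomes.

A disease effector counts as *reverted* when the model predicts its
activity in the direction opposite to the one that induces the disease,
with magnitude strictly above half the achievable maximum (|a| > 0.5).
The tSignal summarises a whole activity profile against a disease
signature as the signed mean of activity x disease sign: -1 means the
signature is fully counteracted, +1 fully reinforced.

Population-level results aggregate per-patient activities per cohort
(cohort-mean activity by default; a per-patient majority rule is available)
and label each reverted gene Adult / Pediatric / Both. Mechanism paths are
interactome paths of at most three edges from a drug target to a strongly
reverted effector (|a| > 0.8), kept only if they qualify in the required
fraction of patients (default 100%) with sign-consistent non-zero weights
along the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from comornet.characterization import DiseaseCharacterization, DrugDefinition, normalize_symbol
from comornet.interactome import Interactome, enumerate_paths
from comornet.netmodel import NetworkModelSolution, ProteinActivity

POPULATION_ADULT = "Adult"
POPULATION_PEDIATRIC = "Pediatric"
POPULATION_BOTH = "Both"

__all__ = [
    "RevertedProteinCall",
    "MechanismPath",
    "MoAReport",
    "MoAError",
    "classify_reverted",
    "compute_tsignal",
    "consensus_reverted",
    "extract_mechanism_paths",
    "load_reverted_table",
    "summarize_reverted_table",
]


class MoAError(ValueError):
    pass


@dataclass(frozen=True)
class RevertedProteinCall:
    gene: str
    disease_sign: int
    predicted_activity: float
    reverted: bool


@dataclass(frozen=True)
class MechanismPath:
    """A <=3-edge path from a drug target to a reverted disease effector."""

    nodes: tuple[str, ...]
    terminal_effector: str
    terminal_activity: float
    frequency: float

    def __post_init__(self) -> None:
        if not (2 <= len(self.nodes) <= 4):
            raise MoAError(f"path must have 1-3 edges, got {len(self.nodes) - 1}")
        if self.nodes[-1] != self.terminal_effector:
            raise MoAError("terminal effector must be the path's last node")


@dataclass(frozen=True)
class MoAReport:
    """Per-population reverted genes, tSignals and filtered mechanism paths."""

    disease_id: str
    reverted: Mapping[str, tuple[str, ...]]  # population label -> genes
    tsignal: Mapping[str, float]  # cohort label -> tSignal
    paths: tuple[MechanismPath, ...] = ()

    @property
    def counts(self) -> dict[str, int]:
        return {pop: len(genes) for pop, genes in self.reverted.items()}


def classify_reverted(
    activity: ProteinActivity,
    disease: DiseaseCharacterization,
    threshold: float = 0.5,
) -> list[RevertedProteinCall]:
    """One call per disease effector; effectors missing from the activity
    map get activity 0 and are not reverted. Both conditions are strict:
    opposite sign and |activity| > threshold."""
    if not (0 < threshold < 1):
        raise MoAError("threshold must be in (0, 1)")
    calls = []
    for eff in sorted(disease.effectors, key=lambda e: e.gene):
        a = activity.get(eff.gene, 0.0)
        reverted = (a * eff.sign < 0) and (abs(a) > threshold)
        calls.append(
            RevertedProteinCall(
                gene=eff.gene,
                disease_sign=eff.sign,
                predicted_activity=a,
                reverted=reverted,
            )
        )
    return calls


def compute_tsignal(activity: ProteinActivity, disease: DiseaseCharacterization) -> float:
    """Signed mean of effector activity x disease sign, in [-1, 1]; negative
    values indicate net reversion of the disease signature."""
    effectors = sorted(disease.effectors, key=lambda e: e.gene)
    if not effectors:
        raise MoAError(f"{disease.disease_id}: empty characterization")
    return float(np.mean([activity.get(e.gene, 0.0) * e.sign for e in effectors]))


def _cohort_mean_activity(activities: Sequence[ProteinActivity], genes: Iterable[str]) -> ProteinActivity:
    values = {
        g: float(np.mean([a.get(g, 0.0) for a in activities])) for g in genes
    }
    return ProteinActivity(values=values)


def consensus_reverted(
    adult_activities: Sequence[ProteinActivity],
    pediatric_activities: Sequence[ProteinActivity],
    disease: DiseaseCharacterization,
    threshold: float = 0.5,
    rule: str = "cohort_mean",
) -> MoAReport:
    """Population-level reversion calls for two cohorts.

    With the default ``cohort_mean`` rule a gene is population-reverted iff
    the cohort-mean activity satisfies the reversion rule; the ``majority``
    rule instead requires a per-patient reverted call in more than half the
    cohort. Genes are labelled Adult / Pediatric / Both.
    """
    if not adult_activities or not pediatric_activities:
        raise MoAError("both cohorts need at least one patient")
    genes = sorted(disease.genes)

    def cohort_reverted(activities: Sequence[ProteinActivity]) -> set[str]:
        if rule == "cohort_mean":
            mean_activity = _cohort_mean_activity(activities, genes)
            return {c.gene for c in classify_reverted(mean_activity, disease, threshold) if c.reverted}
        if rule == "majority":
            votes = {g: 0 for g in genes}
            for act in activities:
                for call in classify_reverted(act, disease, threshold):
                    votes[call.gene] += int(call.reverted)
            return {g for g, v in votes.items() if v > len(activities) / 2}
        raise MoAError(f"unknown consensus rule {rule!r}")

    adult = cohort_reverted(adult_activities)
    pediatric = cohort_reverted(pediatric_activities)
    reverted = {
        POPULATION_ADULT: tuple(sorted(adult)),
        POPULATION_PEDIATRIC: tuple(sorted(pediatric)),
        POPULATION_BOTH: tuple(sorted(adult & pediatric)),
    }
    tsignal = {
        "adult": float(np.mean([compute_tsignal(a, disease) for a in adult_activities])),
        "pediatric-adolescent": float(
            np.mean([compute_tsignal(a, disease) for a in pediatric_activities])
        ),
    }
    return MoAReport(disease_id=disease.disease_id, reverted=reverted, tsignal=tsignal)


def _path_sign_consistent(
    path: Sequence[str],
    weights: Mapping[tuple[str, str], float],
    net: Interactome,
    initial_sign: int,
    terminal_sign: int,
) -> bool:
    """Every traversed edge has non-zero weight and the product of weight
    signs propagates the initial target effect into the observed terminal
    sign."""
    product = 1
    for a, b in zip(path, path[1:]):
        w = weights.get((a, b))
        if w is None:
            w = weights.get((b, a))
            if w is not None:
                edge = net.edge_between(a, b)
                if edge is None or edge.directed:
                    return False
        if w is None or w == 0:
            return False
        product *= 1 if w > 0 else -1
    return product == initial_sign * terminal_sign


def extract_mechanism_paths(
    solutions: Sequence[NetworkModelSolution],
    activities: Sequence[ProteinActivity],
    drug: DrugDefinition,
    disease: DiseaseCharacterization,
    net: Interactome,
    activation_min: float = 0.8,
    frequency_min: float = 1.0,
    max_edges: int = 3,
) -> list[MechanismPath]:
    """Filtered mechanism paths across a population of patient models.

    ``solutions`` and ``activities`` are parallel per-patient sequences. A
    path from a drug target to a disease effector qualifies in one patient
    iff the effector is reverted there with |activity| > activation_min and
    every edge along the path carries non-zero, sign-consistent weight; it
    is kept iff its qualification frequency over patients reaches
    ``frequency_min``.
    """
    if not solutions:
        raise MoAError("no solutions supplied")
    if len(solutions) != len(activities):
        raise MoAError("solutions and activities must be parallel per-patient sequences")
    if not (0 < activation_min < 1) or not (0 < frequency_min <= 1):
        raise MoAError("thresholds must be in (0, 1]")

    targets = set(drug.targets)
    effectors = {e.gene: e.sign for e in disease.effectors}
    all_paths = enumerate_paths(net, targets, set(effectors), max_edges=max_edges)

    kept: list[MechanismPath] = []
    n_patients = len(solutions)
    for path in all_paths:
        terminal = path[-1]
        disease_sign = effectors[terminal]
        initial_sign = drug.targets[path[0]]
        qualifying = 0
        terminal_acts = []
        for solution, activity in zip(solutions, activities):
            a = activity.get(terminal, 0.0)
            strongly_reverted = (a * disease_sign < 0) and (abs(a) > activation_min)
            if not strongly_reverted:
                continue
            terminal_sign = 1 if a > 0 else -1
            if _path_sign_consistent(path, solution.edge_weights, net, initial_sign, terminal_sign):
                qualifying += 1
                terminal_acts.append(a)
        frequency = qualifying / n_patients
        if frequency >= frequency_min:
            kept.append(
                MechanismPath(
                    nodes=tuple(path),
                    terminal_effector=terminal,
                    terminal_activity=float(np.mean(terminal_acts)),
                    frequency=frequency,
                )
            )
    return kept


# -- published-table bookkeeping --------------------------------------------


def load_reverted_table(path: str | Path) -> pd.DataFrame:
    """Load a reverted-protein table (gene, motives, adhd_effector and
    optionally population) as shipped in the packaged fixtures."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "motives", "adhd_effector"}
    missing = required - set(frame.columns)
    if missing:
        raise MoAError(f"{path}: missing columns {sorted(missing)}")
    frame["gene_symbol"] = [normalize_symbol(g)[0] for g in frame["gene"]]
    frame["adhd_effector"] = frame["adhd_effector"].str.strip().str.lower().isin({"yes", "true", "1"})
    if "population" in frame.columns:
        frame["population"] = frame["population"].str.strip()
    return frame


def summarize_reverted_table(frame: pd.DataFrame) -> dict[str, int]:
    """Reverted-protein counts from a published-style table.

    Returns total and ADHD-flagged counts, plus adult/pediatric population
    counts if a population column (Adult / Pediatric / Both) is present: a
    gene counts for a population if flagged for it or for Both.
    """
    out = {
        "total": int(len(frame)),
        "adhd_effectors": int(frame["adhd_effector"].sum()),
    }
    if "population" in frame.columns:
        pops = frame["population"]
        out["adult"] = int(((pops == POPULATION_ADULT) | (pops == POPULATION_BOTH)).sum())
        out["pediatric"] = int(((pops == POPULATION_PEDIATRIC) | (pops == POPULATION_BOTH)).sum())
        out["both"] = int((pops == POPULATION_BOTH).sum())
    return out


def write_moa_tables(report: MoAReport, disease: DiseaseCharacterization, outdir: str | Path) -> None:
    """Write the report as JSON-ready TSV tables (gene, motives, population)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    adult = set(report.reverted.get(POPULATION_ADULT, ()))
    pediatric = set(report.reverted.get(POPULATION_PEDIATRIC, ()))
    for gene in sorted(adult | pediatric):
        eff = disease.effector(gene)
        pop = POPULATION_BOTH if gene in adult and gene in pediatric else (
            POPULATION_ADULT if gene in adult else POPULATION_PEDIATRIC
        )
        rows.append(
            {
                "gene": gene,
                "motives": "/".join(sorted(eff.motives)),
                "population": pop,
            }
        )
    pd.DataFrame(rows, columns=["gene", "motives", "population"]).to_csv(
        outdir / f"reverted_{report.disease_id}.tsv", sep="\t", index=False
    )
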