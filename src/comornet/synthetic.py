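"""Synthetic data generators and packaged fixtures.

The generators emulate the structure of a real study's inputs so every
pipeline stage is testable offline: a scale-free interactome (preferential
attachment) with a controlled fraction of signed/directed edges; disease
characterizations of signed effectors with controlled pairwise overlap to a
base disease (and, optionally, a controlled base-vs-union coverage, the
regime in which roughly half of a base disease's effectors are shared with
at least one comorbidity); and training restrictions generated by
propagating random stimuli through a ground-truth weight vector, hence
satisfiable by construction.

Packaged fixtures transcribe the published drug-target and reverted-protein
tables (drug targets with signs; reverted effectors with motives,
ADHD-effector flags and population labels).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from comornet.characterization import DiseaseCharacterization, EffectorProtein
from comornet.interactome import Edge, Interactome
from comornet.netmodel import PropagationEngine, TrainingRestriction

__all__ = [
    "SynthSpec",
    "SynthError",
    "synth_interactome",
    "synth_characterizations",
    "synth_restrictions",
    "fixture_path",
    "gene_name",
]


class SynthError(ValueError):
    pass


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV/YAML under comornet/data."""
    return Path(str(resources.files("comornet").joinpath("data", name)))


def gene_name(i: int) -> str:
    """Deterministic synthetic gene symbol G0000, G0001, ..."""
    return f"G{i:04d}"


@dataclass(frozen=True)
class SynthSpec:
    """Specification for one synthetic study universe.

    ``overlap_with_base``: for each non-base disease, the requested fraction
    of the base disease's effectors it shares. ``base_union_overlap``: if
    set, the fraction of base effectors shared with at least one other
    disease (the per-pair shares are then drawn from within that covered
    subset). ``signed_fraction``/``directed_fraction``: fraction of edges
    given a random activation/inhibition sign, resp. a direction.
    """

    n_nodes: int = 1000
    attachment: int = 3
    n_diseases: int = 6
    effectors_per_disease: int = 60
    overlap_with_base: tuple[float, ...] = (0.34, 0.20, 0.15, 0.12, 0.08)
    base_union_overlap: float | None = 0.53
    signed_fraction: float = 0.3
    directed_fraction: float = 0.2
    n_motives: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.attachment < 1:
            raise SynthError("need n_nodes >= 2 and attachment >= 1")
        if self.n_diseases < 1 or self.effectors_per_disease < 1:
            raise SynthError("need at least one disease and one effector")
        if len(self.overlap_with_base) != self.n_diseases - 1:
            raise SynthError("overlap_with_base must have n_diseases - 1 entries")
        for frac in self.overlap_with_base:
            if not (0 <= frac <= 1):
                raise SynthError("overlap fractions must be in [0, 1]")
        if self.base_union_overlap is not None and not (0 <= self.base_union_overlap <= 1):
            raise SynthError("base_union_overlap must be in [0, 1]")
        if not (0 <= self.signed_fraction <= 1) or not (0 <= self.directed_fraction <= 1):
            raise SynthError("edge annotation fractions must be in [0, 1]")
        if self.n_nodes < self.n_diseases * self.effectors_per_disease:
            raise SynthError("n_nodes must cover all distinct effectors")


def synth_interactome(spec: SynthSpec) -> Interactome:
    """Scale-free interactome by preferential attachment; a declared
    fraction of edges is randomly signed and/or directed; seeded."""
    rng = np.random.default_rng(spec.seed)
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=int(rng.integers(2**31)))
    edges = []
    for a, b in sorted(g.edges()):
        sign = int(rng.choice([-1, 1])) if rng.uniform() < spec.signed_fraction else 0
        directed = bool(rng.uniform() < spec.directed_fraction)
        if directed and rng.uniform() < 0.5:
            a, b = b, a
        edges.append(Edge(gene_name(a), gene_name(b), directed=directed, sign=sign))
    return Interactome(edges=edges, nodes=(gene_name(i) for i in range(spec.n_nodes)))


def _build_effector_sets(spec: SynthSpec, rng: np.random.Generator, pool: list[str]) -> list[set[str]]:
    n_eff = spec.effectors_per_disease
    pool = list(pool)
    rng.shuffle(pool)
    cursor = 0

    def take(count: int) -> list[str]:
        nonlocal cursor
        if cursor + count > len(pool):
            raise SynthError("infeasible overlap matrix: effector pool exhausted")
        out = pool[cursor : cursor + count]
        cursor += count
        return out

    base = set(take(n_eff))
    base_list = sorted(base)
    shares = [int(round(frac * n_eff)) for frac in spec.overlap_with_base]

    if spec.base_union_overlap is None:
        # no union-coverage target: each disease samples its share freely
        assignments = [
            [str(g) for g in rng.choice(base_list, size=share, replace=False)]
            for share in shares
        ]
        sets = [base]
        for share_genes in assignments:
            own = take(n_eff - len(share_genes))
            sets.append(set(share_genes) | set(own))
        return sets
    else:
        n_cov = int(round(spec.base_union_overlap * n_eff))
        if sum(shares) < n_cov:
            raise SynthError(
                "infeasible overlap matrix: pairwise shares cannot cover the requested union"
            )
        covered = list(rng.choice(base_list, size=n_cov, replace=False))

    # distribute the covered base effectors over the other diseases so every
    # covered gene is shared at least once and pairwise quotas are met
    assignments: list[list[str]] = [[] for _ in shares]
    order = sorted(range(len(shares)), key=lambda i: -shares[i])
    covered_cycle = list(covered)
    pos = 0
    for i in order:
        quota = shares[i]
        picks: list[str] = []
        while len(picks) < quota and pos < len(covered_cycle):
            picks.append(covered_cycle[pos])
            pos += 1
        if len(picks) < quota:
            remaining = [g for g in covered if g not in picks]
            if quota - len(picks) > len(remaining):
                raise SynthError(
                    "infeasible overlap matrix: a pairwise share exceeds the union coverage"
                )
            extra = rng.choice(remaining, size=quota - len(picks), replace=False)
            picks.extend(str(g) for g in extra)
        assignments[i] = picks
    if pos < len(covered_cycle):
        raise SynthError("infeasible overlap matrix: union target exceeds pairwise shares")

    sets = [base]
    for i, share_genes in enumerate(assignments):
        own = take(n_eff - len(share_genes))
        sets.append(set(share_genes) | set(own))
    return sets


def synth_characterizations(spec: SynthSpec, net: Interactome) -> list[DiseaseCharacterization]:
    """Disease characterizations with controlled overlap to the base disease
    (disease_0); signs random, motives assigned round-robin."""
    rng = np.random.default_rng(spec.seed + 1)
    pool = sorted(net.nodes)
    if len(pool) < spec.n_diseases * spec.effectors_per_disease:
        raise SynthError("network too small for the requested characterizations")
    sets = _build_effector_sets(spec, rng, pool)
    motive_labels = [f"motive_{string.ascii_lowercase[i]}" for i in range(spec.n_motives)]
    diseases = []
    for d_idx, genes in enumerate(sets):
        effectors = []
        for g_idx, gene in enumerate(sorted(genes)):
            effectors.append(
                EffectorProtein(
                    gene=gene,
                    sign=int(rng.choice([-1, 1])),
                    motives=frozenset({motive_labels[g_idx % spec.n_motives]}),
                )
            )
        diseases.append(
            DiseaseCharacterization(
                disease_id=f"disease_{d_idx}",
                motives=tuple(motive_labels),
                effectors=frozenset(effectors),
            )
        )
    return diseases


def synth_restrictions(
    net: Interactome,
    ground_truth_weights: Mapping[tuple[str, str], float] | np.ndarray,
    n_restrictions: int,
    seed: int = 0,
    n_stimulus_genes: int = 2,
    n_response_genes: int = 5,
    n_steps: int = 3,
    min_response_magnitude: float = 0.1,
    engine: PropagationEngine | None = None,
) -> list[TrainingRestriction]:
    """Training restrictions generated from a ground-truth model.

    Random signed stimuli are propagated through the ground-truth weights;
    each restriction's expected responses are the signs of sampled
    downstream nodes whose activity magnitude exceeds
    ``min_response_magnitude``, so the set is satisfiable by construction.
    """
    if n_restrictions == 0:
        return []
    eng = engine or PropagationEngine(net)
    weights = (
        ground_truth_weights
        if isinstance(ground_truth_weights, np.ndarray)
        else eng.weights_from_mapping(ground_truth_weights)
    )
    rng = np.random.default_rng(seed)
    nodes = eng.node_order
    restrictions: list[TrainingRestriction] = []
    attempts = 0
    while len(restrictions) < n_restrictions:
        attempts += 1
        if attempts > 50 * n_restrictions:
            raise SynthError("could not find enough responsive stimuli; weights too weak")
        stim_genes = rng.choice(nodes, size=min(n_stimulus_genes, len(nodes)), replace=False)
        stimulus = {str(g): int(rng.choice([-1, 1])) for g in stim_genes}
        s, mask = eng.stimulus_vector({g: float(v) for g, v in stimulus.items()})
        a = eng.propagate_many(weights, s[:, None], mask[:, None], n_steps)[:, 0]
        candidates = [
            i
            for i in np.argsort(-np.abs(a))
            if abs(a[i]) > min_response_magnitude and nodes[i] not in stimulus
        ]
        if len(candidates) < n_response_genes:
            continue
        pick = rng.choice(len(candidates), size=n_response_genes, replace=False)
        response = {nodes[candidates[i]]: (1 if a[candidates[i]] > 0 else -1) for i in pick}
        restrictions.append(
            TrainingRestriction(
                stimulus=stimulus,
                expected_response=response,
                tag=f"synthetic_{len(restrictions)}",
            )
        )
    return restrictions
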