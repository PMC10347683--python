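"""Sampled signed-propagation network models.

Each model is a weight vector over the interactome's edges (weights in
[-1, 1]; edges annotated with a known activation/inhibition sign are
constrained to that sign's half-interval). Protein activity spreads from a
stimulus by a clamped synchronous update

    a(t+1) = tanh( s + W^T a(t) ),    a(0) = s,

with stimulus nodes held at their stimulus value, so all activities stay in
[-1, 1]. Model quality is the training-set accuracy: the fraction of
expected response signs reproduced (outside a small dead zone) when each
training stimulus is propagated. Solutions are drawn by seeded random
initialisation plus coordinate hill-climbing on a continuous compliance
margin, and accepted only if accuracy reaches the viability floor
(default 0.85).

Drug exposure enters through an Emax-type stimulus: each drug target
receives magnitude effect * C/(C + EC50) with C taken from the patient's
brain concentration curve.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix

from comornet.characterization import DrugDefinition
from comornet.interactome import Interactome
from comornet.pbpk import ConcentrationCurve

DEFAULT_N_STEPS = 3
DEFAULT_DEAD_ZONE = 0.05
DEFAULT_ACCURACY_MIN = 0.85

__all__ = [
    "TrainingRestriction",
    "NetworkModelSolution",
    "NetModelError",
    "InfeasibleSamplingError",
    "propagate",
    "restriction_accuracy",
    "sample_solutions",
    "drug_stimulus",
    "PropagationEngine",
]


class NetModelError(ValueError):
    pass


class InfeasibleSamplingError(RuntimeError):
    """Raised when the acceptance quota cannot be met within the draw budget."""


@dataclass(frozen=True)
class TrainingRestriction:
    """One stimulus -> expected-response pair from the training set."""

    stimulus: Mapping[str, int]
    expected_response: Mapping[str, int]
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.stimulus or not self.expected_response:
            raise NetModelError(f"{self.tag or 'restriction'}: stimulus and response must be non-empty")
        for mapping in (self.stimulus, self.expected_response):
            for gene, sign in mapping.items():
                if sign not in (-1, 1):
                    raise NetModelError(f"{self.tag or 'restriction'}: sign for {gene} must be -1/+1")


@dataclass(frozen=True)
class NetworkModelSolution:
    """An accepted sampled model: per-edge weights plus its training accuracy."""

    edge_weights: Mapping[tuple[str, str], float]
    n_steps: int
    accuracy: float
    seed: int
    patient_id: str | None = None


@dataclass(frozen=True)
class ProteinActivity:
    """Node activities in [-1, 1] predicted by one model under one stimulus."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if not -1.0 <= v <= 1.0}
        if bad:
            raise NetModelError(f"activities outside [-1, 1]: {bad}")

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.values.get(gene, default)


class PropagationEngine:
    """Caches the node indexing and edge->matrix entries for one interactome.

    Weight vectors are ordered as ``net.edges``; undirected edges contribute
    symmetric matrix entries.
    """

    def __init__(self, net: Interactome):
        self.net = net
        self.node_order = sorted(net.nodes)
        self.index = {g: i for i, g in enumerate(self.node_order)}
        self.edges = net.edges
        rows, cols, owner = [], [], []
        for e_idx, edge in enumerate(self.edges):
            i, j = self.index[edge.source], self.index[edge.target]
            rows.append(j)
            cols.append(i)
            owner.append(e_idx)
            if not edge.directed and i != j:
                rows.append(i)
                cols.append(j)
                owner.append(e_idx)
        self._rows = np.asarray(rows, dtype=np.int64)
        self._cols = np.asarray(cols, dtype=np.int64)
        self._owner = np.asarray(owner, dtype=np.int64)
        self.edge_signs = np.asarray([e.sign for e in self.edges], dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def matrix(self, weights: np.ndarray) -> csr_matrix:
        data = weights[self._owner]
        n = self.n_nodes
        return csr_matrix((data, (self._rows, self._cols)), shape=(n, n))

    def stimulus_vector(self, stimulus: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
        s = np.zeros(self.n_nodes)
        mask = np.zeros(self.n_nodes, dtype=bool)
        for gene, value in stimulus.items():
            if not -1.0 <= value <= 1.0:
                raise NetModelError(f"stimulus magnitude for {gene} outside [-1, 1]")
            idx = self.index.get(gene)
            if idx is not None:
                s[idx] = value
                mask[idx] = True
        return s, mask

    def propagate_many(
        self,
        weights: np.ndarray,
        stimuli: np.ndarray,
        clamp_mask: np.ndarray,
        n_steps: int,
    ) -> np.ndarray:
        """Propagate a (n_nodes, n_stimuli) stimulus matrix; returns activities."""
        m = self.matrix(weights)
        a = stimuli.copy()
        for _ in range(n_steps):
            a = np.tanh(stimuli + m @ a)
            a[clamp_mask] = stimuli[clamp_mask]
        return a

    def weights_from_mapping(self, mapping: Mapping[tuple[str, str], float]) -> np.ndarray:
        lookup = {}
        for edge_idx, edge in enumerate(self.edges):
            lookup[(edge.source, edge.target)] = edge_idx
            if not edge.directed:
                lookup[(edge.target, edge.source)] = edge_idx
        w = np.zeros(self.n_edges)
        for (a, b), value in mapping.items():
            idx = lookup.get((a, b))
            if idx is None:
                raise NetModelError(f"weight on non-existent edge ({a}, {b})")
            w[idx] = value
        return w

    def weights_to_mapping(self, weights: np.ndarray) -> dict[tuple[str, str], float]:
        return {
            (edge.source, edge.target): float(weights[i]) for i, edge in enumerate(self.edges)
        }

    def random_weights(self, rng: np.random.Generator) -> np.ndarray:
        w = rng.uniform(-1.0, 1.0, size=self.n_edges)
        signed = self.edge_signs != 0
        w[signed] = np.abs(w[signed]) * self.edge_signs[signed]
        return w


def propagate(
    net: Interactome,
    weights: Mapping[tuple[str, str], float] | np.ndarray,
    stimulus: Mapping[str, float],
    n_steps: int = DEFAULT_N_STEPS,
    engine: PropagationEngine | None = None,
) -> ProteinActivity:
    """Clamped signed propagation of a stimulus through weighted edges.

    Stimulus genes absent from the network are ignored. Raises on weights
    that name non-existent edges.
    """
    if n_steps < 1:
        raise NetModelError("n_steps must be >= 1")
    eng = engine or PropagationEngine(net)
    w = weights if isinstance(weights, np.ndarray) else eng.weights_from_mapping(weights)
    s, mask = eng.stimulus_vector(stimulus)
    a = eng.propagate_many(w, s[:, None], mask[:, None], n_steps)[:, 0]
    return ProteinActivity(values={g: float(a[i]) for g, i in eng.index.items()})


def _restriction_arrays(
    engine: PropagationEngine,
    restrictions: Sequence[TrainingRestriction],
) -> tuple[np.ndarray, np.ndarray, list[list[tuple[int, int]]]]:
    n = engine.n_nodes
    stimuli = np.zeros((n, len(restrictions)))
    masks = np.zeros((n, len(restrictions)), dtype=bool)
    responses: list[list[tuple[int, int]]] = []
    for r_idx, restriction in enumerate(restrictions):
        s, mask = engine.stimulus_vector({g: float(v) for g, v in restriction.stimulus.items()})
        stimuli[:, r_idx] = s
        masks[:, r_idx] = mask
        pairs = [
            (engine.index[g], sign)
            for g, sign in restriction.expected_response.items()
            if g in engine.index
        ]
        responses.append(pairs)
    return stimuli, masks, responses


def _score_activities(
    activities: np.ndarray,
    responses: list[list[tuple[int, int]]],
    dead_zone: float,
) -> tuple[float, float]:
    """(accuracy, continuous margin objective) of propagated activities."""
    per_restriction = []
    margins = []
    for r_idx, pairs in enumerate(responses):
        if not pairs:
            per_restriction.append(0.0)
            continue
        hits = 0
        for node_idx, sign in pairs:
            a = activities[node_idx, r_idx]
            margins.append(sign * a)
            if sign * a > dead_zone:
                hits += 1
        per_restriction.append(hits / len(pairs))
    accuracy = float(np.mean(per_restriction)) if per_restriction else 0.0
    margin = float(np.mean(margins)) if margins else 0.0
    return accuracy, margin


def restriction_accuracy(
    solution: NetworkModelSolution | Mapping[tuple[str, str], float] | np.ndarray,
    restrictions: Sequence[TrainingRestriction],
    net: Interactome,
    n_steps: int | None = None,
    dead_zone: float = DEFAULT_DEAD_ZONE,
    engine: PropagationEngine | None = None,
) -> float:
    """Training-set compliance: mean over restrictions of the fraction of
    expected response genes whose propagated activity matches the expected
    sign with magnitude above the dead zone."""
    if not restrictions:
        raise NetModelError("at least one restriction required")
    eng = engine or PropagationEngine(net)
    if isinstance(solution, NetworkModelSolution):
        weights = eng.weights_from_mapping(solution.edge_weights)
        steps = n_steps if n_steps is not None else solution.n_steps
    else:
        weights = solution if isinstance(solution, np.ndarray) else eng.weights_from_mapping(solution)
        steps = n_steps if n_steps is not None else DEFAULT_N_STEPS
    stimuli, masks, responses = _restriction_arrays(eng, restrictions)
    activities = eng.propagate_many(weights, stimuli, masks, steps)
    accuracy, _ = _score_activities(activities, responses, dead_zone)
    return accuracy


def _candidate_edges(
    engine: PropagationEngine,
    restrictions: Sequence[TrainingRestriction],
    n_steps: int,
) -> np.ndarray:
    """Edges reachable within n_steps of any stimulus node; only these can
    influence the training responses."""
    net = engine.net
    frontier = {g for r in restrictions for g in r.stimulus if g in net}
    reachable: dict[str, int] = {g: 0 for g in frontier}
    queue = deque(frontier)
    while queue:
        node = queue.popleft()
        depth = reachable[node]
        if depth >= n_steps - 1:
            continue
        for nxt in net.successors(node):
            if nxt not in reachable:
                reachable[nxt] = depth + 1
                queue.append(nxt)
    idx = []
    for e_idx, edge in enumerate(engine.edges):
        if edge.source in reachable or (not edge.directed and edge.target in reachable):
            idx.append(e_idx)
    return np.asarray(idx, dtype=np.int64)


def sample_solutions(
    net: Interactome,
    restrictions: Sequence[TrainingRestriction],
    n_accept: int,
    accuracy_min: float = DEFAULT_ACCURACY_MIN,
    seed: int = 0,
    max_draws: int = 200,
    n_steps: int = DEFAULT_N_STEPS,
    dead_zone: float = DEFAULT_DEAD_ZONE,
    max_passes: int = 8,
    patient_id: str | None = None,
    engine: PropagationEngine | None = None,
) -> list[NetworkModelSolution]:
    """Draw accepted network-model solutions.

    Each draw starts from a random weight vector (uniform per edge, signed
    edges restricted to their half-interval) and is refined by coordinate
    hill-climbing on the mean compliance margin; it is accepted iff its
    training accuracy reaches ``accuracy_min``. Raises
    :class:`InfeasibleSamplingError` if the quota is not met in
    ``max_draws`` draws.
    """
    if not (0 < accuracy_min <= 1):
        raise NetModelError("accuracy_min must be in (0, 1]")
    if max_draws < n_accept:
        raise NetModelError("max_draws must be >= n_accept")
    if not restrictions:
        raise NetModelError("at least one restriction required")
    eng = engine or PropagationEngine(net)
    stimuli, masks, responses = _restriction_arrays(eng, restrictions)
    candidates = _candidate_edges(eng, restrictions, n_steps)
    rng = np.random.default_rng(seed)
    signs = eng.edge_signs

    def evaluate(w: np.ndarray) -> tuple[float, float]:
        activities = eng.propagate_many(w, stimuli, masks, n_steps)
        return _score_activities(activities, responses, dead_zone)

    accepted: list[NetworkModelSolution] = []
    for draw in range(max_draws):
        w = eng.random_weights(rng)
        acc, obj = evaluate(w)
        for _ in range(max_passes):
            if acc >= accuracy_min:
                break
            improved = False
            for e_idx in rng.permutation(candidates):
                proposal = rng.uniform(0.05, 1.0)
                if signs[e_idx] != 0:
                    trials = (signs[e_idx] * proposal,)
                else:
                    trials = (proposal, -proposal)
                old = w[e_idx]
                best_obj, best_acc, best_val = obj, acc, old
                for value in trials:
                    w[e_idx] = value
                    t_acc, t_obj = evaluate(w)
                    if (t_acc, t_obj) > (best_acc, best_obj):
                        best_obj, best_acc, best_val = t_obj, t_acc, value
                w[e_idx] = best_val
                if best_val != old:
                    acc, obj = best_acc, best_obj
                    improved = True
                if acc >= accuracy_min:
                    break
            if not improved:
                break
        if acc >= accuracy_min:
            accepted.append(
                NetworkModelSolution(
                    edge_weights=eng.weights_to_mapping(w),
                    n_steps=n_steps,
                    accuracy=acc,
                    seed=seed,
                    patient_id=patient_id,
                )
            )
            if len(accepted) == n_accept:
                return accepted
    raise InfeasibleSamplingError(
        f"infeasible: acceptance quota not met within {max_draws} draws "
        f"({len(accepted)}/{n_accept} accepted at accuracy_min={accuracy_min})"
    )


def load_restrictions(path) -> list[TrainingRestriction]:
    """Load training restrictions from YAML/JSON: a list of objects with
    ``stimulus`` and ``response`` gene->sign maps and an optional ``tag``."""
    import yaml

    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, list):
        raise NetModelError(f"{path}: expected a list of restrictions")
    out = []
    for i, item in enumerate(raw):
        out.append(
            TrainingRestriction(
                stimulus={str(g).upper(): int(v) for g, v in item["stimulus"].items()},
                expected_response={str(g).upper(): int(v) for g, v in item["response"].items()},
                tag=str(item.get("tag", f"restriction_{i}")),
            )
        )
    return out


def write_restrictions(restrictions: Sequence[TrainingRestriction], path) -> None:
    import yaml

    payload = [
        {
            "stimulus": dict(r.stimulus),
            "response": dict(r.expected_response),
            "tag": r.tag,
        }
        for r in restrictions
    ]
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(payload, handle, sort_keys=True)


def drug_stimulus(
    drug: DrugDefinition,
    curve: ConcentrationCurve,
    ec50: float,
    timepoint_policy: str = "cmax",
) -> dict[str, float]:
    """Emax-type target modulation from a brain exposure curve.

    Each target's stimulus magnitude is ``effect * C/(C + EC50)`` with C the
    brain concentration under the chosen policy ("cmax", "mean" or
    "trough"), so magnitudes saturate at the target effect sign.
    """
    if curve.tissue != "brain":
        raise NetModelError(f"drug stimulus requires the brain curve, got {curve.tissue!r}")
    if ec50 <= 0:
        raise NetModelError("ec50 must be positive")
    if not drug.targets:
        raise NetModelError("drug has no targets")
    if timepoint_policy == "cmax":
        c = curve.cmax
    elif timepoint_policy == "mean":
        c = float(np.mean(curve.concentrations))
    elif timepoint_policy == "trough":
        c = float(curve.concentrations[-1])
    else:
        raise NetModelError(f"unknown timepoint policy {timepoint_policy!r}")
    occupancy = c / (c + ec50)
    return {gene: effect * occupancy for gene, effect in drug.targets.items()}
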