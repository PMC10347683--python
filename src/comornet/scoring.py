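"""Target-set to effector-set relationship scoring.

The statistic is closest-distance network proximity: the mean over drug
targets of the shortest undirected path length to the disease effector set.
Significance is assessed against a degree-matched permutation null (random
target sets of the same size drawn from logarithmic degree bins), giving an
empirical p-value, which is mapped onto a 0-100 relationship score through a
piecewise-linear curve in log10(p) anchored at the published p/score band
boundaries:

    p = 0.001 -> 100,  0.01 -> 92,  0.05 -> 77,  0.25 -> 37,  1.0 -> 0

and the score bands very_high (>= 92), high ([77, 92)), medium ([37, 77)),
low (< 37) correspond to p < 0.01, < 0.05, < 0.25 and >= 0.25.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from comornet.interactome import Interactome

SCORE_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.001, 100.0),
    (0.01, 92.0),
    (0.05, 77.0),
    (0.25, 37.0),
    (1.0, 0.0),
)

BAND_VERY_HIGH = "very_high"
BAND_HIGH = "high"
BAND_MEDIUM = "medium"
BAND_LOW = "low"

__all__ = [
    "RelationshipScore",
    "ScoringError",
    "proximity_statistic",
    "empirical_score",
    "categorize_score",
    "score_from_p",
    "write_score_report",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class RelationshipScore:
    raw_stat: float
    empirical_p: float
    score: float
    band: str


def _distances_to_set(net: Interactome, effectors: set[str]) -> dict[str, int]:
    """Multi-source BFS distances from every node to the nearest effector."""
    seeds = [g for g in effectors if g in net]
    dist = {g: 0 for g in seeds}
    queue = deque(seeds)
    while queue:
        node = queue.popleft()
        d = dist[node]
        for nb in net.neighbors(node):
            if nb not in dist:
                dist[nb] = d + 1
                queue.append(nb)
    return dist


def _stat_from_distances(targets: Iterable[str], dist: dict[str, int], d_cap: int) -> float:
    values = [min(dist.get(g, d_cap), d_cap) for g in targets]
    return float(np.mean(values))


def proximity_statistic(targets: set[str], effectors: set[str], net: Interactome) -> float:
    """Mean over targets of the minimum shortest-path distance to the
    effector set (direction ignored); targets disconnected from every
    effector contribute the capped distance ``diameter + 1``."""
    if not targets:
        raise ScoringError("empty target set")
    if not effectors:
        raise ScoringError("empty effector set")
    d_cap = net.diameter() + 1
    dist = _distances_to_set(net, set(effectors))
    return _stat_from_distances(targets, dist, d_cap)


def score_from_p(p: float) -> float:
    """Piecewise-linear map from p-value to 0-100 score in log10(p) space."""
    if not (0 < p <= 1):
        raise ScoringError(f"p-value {p} outside (0, 1]")
    logp = math.log10(p)
    anchors = [(math.log10(pa), sa) for pa, sa in SCORE_ANCHORS]
    if logp <= anchors[0][0]:
        return 100.0
    for (x0, y0), (x1, y1) in zip(anchors, anchors[1:]):
        if logp <= x1:
            t = (logp - x0) / (x1 - x0)
            return float(min(100.0, max(0.0, y0 + t * (y1 - y0))))
    return 0.0


def categorize_score(score: float) -> str:
    """Band label for a 0-100 relationship score (upper-half-open bands,
    top band closed)."""
    if not (0 <= score <= 100):
        raise ScoringError(f"score {score} outside [0, 100]")
    if score >= 92:
        return BAND_VERY_HIGH
    if score >= 77:
        return BAND_HIGH
    if score >= 37:
        return BAND_MEDIUM
    return BAND_LOW


def _degree_bins(net: Interactome) -> dict[int, list[str]]:
    """Nodes grouped into logarithmic degree bins of width factor 2."""
    bins: dict[int, list[str]] = {}
    for node in sorted(net.nodes):
        deg = net.degree(node)
        key = -1 if deg == 0 else int(math.floor(math.log2(deg)))
        bins.setdefault(key, []).append(node)
    return bins


def sample_degree_matched(
    net: Interactome,
    template: Sequence[str],
    rng: np.random.Generator,
    bins: dict[int, list[str]] | None = None,
) -> list[str]:
    """A random node set matching the template's size and degree-bin profile.

    Nodes are drawn without replacement within the sampled set; a bin whose
    distinct candidates run out falls back to the neighbouring bins.
    """
    if bins is None:
        bins = _degree_bins(net)
    chosen: list[str] = []
    taken: set[str] = set()
    for gene in template:
        deg = net.degree(gene)
        key = -1 if deg == 0 else int(math.floor(math.log2(deg)))
        candidates = [n for n in bins.get(key, ()) if n not in taken]
        if not candidates:
            for offset in (1, -1, 2, -2, 3, -3):
                candidates = [n for n in bins.get(key + offset, ()) if n not in taken]
                if candidates:
                    break
        if not candidates:
            candidates = [n for n in sorted(net.nodes) if n not in taken]
        pick = candidates[int(rng.integers(len(candidates)))]
        chosen.append(pick)
        taken.add(pick)
    return chosen


def empirical_score(
    stat: float,
    targets: set[str],
    effectors: set[str],
    net: Interactome,
    n_null: int = 999,
    seed: int = 0,
) -> RelationshipScore:
    """Score a proximity statistic against a degree-matched null.

    ``empirical_p = (1 + #{null stats <= stat}) / (n_null + 1)``; the score
    is the anchored piecewise-linear map of the p-value.
    """
    if n_null < 19:
        raise ScoringError(f"n_null must be >= 19, got {n_null}")
    effectors_in_net = {g for g in effectors if g in net}
    if not effectors_in_net:
        raise ScoringError("no effector is present in the network")
    rng = np.random.default_rng(seed)
    d_cap = net.diameter() + 1
    dist = _distances_to_set(net, effectors_in_net)
    bins = _degree_bins(net)
    template = sorted(targets)
    n_le = 0
    for _ in range(n_null):
        null_set = sample_degree_matched(net, template, rng, bins)
        if _stat_from_distances(null_set, dist, d_cap) <= stat:
            n_le += 1
    p = (1 + n_le) / (n_null + 1)
    score = score_from_p(p)
    return RelationshipScore(raw_stat=float(stat), empirical_p=p, score=score, band=categorize_score(score))


def write_score_report(
    rows: Iterable[tuple[str, str, RelationshipScore]],
    path: str | Path,
) -> None:
    """TSV report: drug_id, disease_id, raw_stat, empirical_p, score, band."""
    lines = ["drug_id\tdisease_id\traw_stat\tempirical_p\tscore\tband"]
    for drug_id, disease_id, rel in rows:
        lines.append(
            f"{drug_id}\t{disease_id}\t{rel.raw_stat:.4f}\t{rel.empirical_p:.6g}\t{rel.score:.2f}\t{rel.band}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
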