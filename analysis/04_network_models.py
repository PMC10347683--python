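#!/usr/bin/env python
"""Stage 4: sampled signed-propagation network models.

On the stage-1 interactome, builds a ground-truth-satisfiable training set
of 20 stimulus/response restrictions and samples 10 accepted model
solutions, reporting the distribution of training accuracies against the
85% viability floor.

Writes: results/analysis/netmodel.json.
"""

import json
from pathlib import Path

import numpy as np

from comornet.interactome import load_edge_dump
from comornet.netmodel import PropagationEngine, sample_solutions
from comornet.synthetic import synth_restrictions

OUT = Path("results/analysis")
SEED = 2026


def main() -> None:
    net = load_edge_dump(OUT / "interactome.tsv")
    engine = PropagationEngine(net)
    rng = np.random.default_rng(SEED + 10)
    truth = engine.random_weights(rng)
    restrictions = synth_restrictions(net, truth, 20, seed=SEED + 11, engine=engine)
    solutions = sample_solutions(
        net, restrictions, n_accept=10, accuracy_min=0.85, seed=SEED + 12, engine=engine
    )
    accuracies = [s.accuracy for s in solutions]
    print(f"accepted {len(solutions)} solutions on {engine.n_nodes} nodes / "
          f"{engine.n_edges} edges")
    print(f"training accuracy: min {min(accuracies):.3f}, "
          f"mean {np.mean(accuracies):.3f}, max {max(accuracies):.3f} "
          f"(floor 0.85)")
    payload = {
        "n_nodes": engine.n_nodes,
        "n_edges": engine.n_edges,
        "n_restrictions": len(restrictions),
        "accuracies": accuracies,
        "min_accuracy": min(accuracies),
        "mean_accuracy": float(np.mean(accuracies)),
    }
    (OUT / "netmodel.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"wrote {OUT / 'netmodel.json'}")


if __name__ == "__main__":
    main()
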