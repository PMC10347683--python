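"""Signed propagation, training-set accuracy, solution sampling, drug stimulus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comornet.characterization import DrugDefinition
from comornet.interactome import Edge, Interactome
from comornet.netmodel import (
    InfeasibleSamplingError,
    NetModelError,
    PropagationEngine,
    TrainingRestriction,
    drug_stimulus,
    propagate,
    restriction_accuracy,
    sample_solutions,
)
from comornet.pbpk import ConcentrationCurve
from comornet.synthetic import SynthSpec, synth_interactome, synth_restrictions


def two_node_net():
    return Interactome(edges=[Edge("A", "B", directed=True)])


class TestPropagate:
    def test_single_step_closed_form(self):
        net = two_node_net()
        act = propagate(net, {("A", "B"): 1.0}, {"A": 1.0}, n_steps=1)
        assert act.get("B") == pytest.approx(np.tanh(1.0))
        assert act.get("A") == 1.0  # clamped stimulus node

    def test_zero_weights_leave_only_stimulus(self, toy_net):
        weights = {(e.source, e.target): 0.0 for e in toy_net.edges}
        act = propagate(toy_net, weights, {"A": 0.7}, n_steps=3)
        assert act.get("A") == pytest.approx(0.7)
        assert all(act.get(g) == 0.0 for g in toy_net.nodes - {"A"})

    def test_matches_independent_matrix_iteration(self, toy_net):
        """Oracle: explicit dense synchronous iteration coded independently."""
        rng = np.random.default_rng(4)
        weights = {(e.source, e.target): float(rng.uniform(-1, 1)) for e in toy_net.edges}
        stimulus = {"A": 0.9, "E": -0.5}
        nodes = sorted(toy_net.nodes)
        idx = {g: i for i, g in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for (a, b), value in weights.items():
            w[idx[b], idx[a]] = value
            w[idx[a], idx[b]] = value  # all toy_net edges are undirected
        s = np.zeros(len(nodes))
        for g, v in stimulus.items():
            s[idx[g]] = v
        a_vec = s.copy()
        for _ in range(3):
            a_vec = np.tanh(s + w @ a_vec)
            for g, v in stimulus.items():
                a_vec[idx[g]] = v
        act = propagate(toy_net, weights, stimulus, n_steps=3)
        for g in nodes:
            assert act.get(g) == pytest.approx(a_vec[idx[g]])

    def test_weight_on_missing_edge_raises(self, toy_net):
        with pytest.raises(NetModelError, match="non-existent edge"):
            propagate(toy_net, {("A", "Z"): 1.0}, {"A": 1.0})

    def test_direction_respected(self):
        net = two_node_net()
        act = propagate(net, {("A", "B"): 1.0}, {"B": 1.0}, n_steps=3)
        assert act.get("A") == 0.0  # no edge B -> A

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n_steps=st.integers(1, 6))
    def test_boundedness_under_random_weights(self, seed, n_steps, medium_net):
        rng = np.random.default_rng(seed)
        eng = PropagationEngine(medium_net)
        w = rng.uniform(-1, 1, eng.n_edges) * rng.uniform(1, 3)  # even out-of-range weights
        genes = sorted(medium_net.nodes)
        stimulus = {genes[int(rng.integers(len(genes)))]: float(rng.uniform(-1, 1))}
        act = propagate(medium_net, w, stimulus, n_steps=n_steps, engine=eng)
        values = np.array(list(act.values.values()))
        assert np.all(values >= -1) and np.all(values <= 1)

    def test_monotone_response_on_positive_chain(self):
        net = Interactome(
            edges=[Edge("A", "B", directed=True), Edge("B", "C", directed=True)]
        )
        weights = {("A", "B"): 0.8, ("B", "C"): 0.8}
        magnitudes = [0.2, 0.5, 0.8, 1.0]
        downstream = [abs(propagate(net, weights, {"A": m}, 3).get("C")) for m in magnitudes]
        assert all(a <= b + 1e-12 for a, b in zip(downstream, downstream[1:]))


class TestRestrictionAccuracy:
    def test_perfect_solution_scores_one(self):
        net = two_node_net()
        weights = {("A", "B"): 1.0}
        restriction = TrainingRestriction(stimulus={"A": 1}, expected_response={"B": 1})
        assert restriction_accuracy(weights, [restriction], net) == 1.0

    def test_half_right_restriction_scores_half(self):
        net = Interactome(
            edges=[Edge("A", "B", directed=True), Edge("A", "C", directed=True)]
        )
        weights = {("A", "B"): 1.0, ("A", "C"): 1.0}
        restriction = TrainingRestriction(
            stimulus={"A": 1}, expected_response={"B": 1, "C": -1}
        )
        assert restriction_accuracy(weights, [restriction], net) == 0.5

    def test_three_restrictions_match_hand_compliance(self, toy_net):
        # fixed weights: all +0.9; undirected toy net
        weights = {(e.source, e.target): 0.9 for e in toy_net.edges}
        restrictions = [
            TrainingRestriction(stimulus={"A": 1}, expected_response={"B": 1}),  # hit
            TrainingRestriction(stimulus={"A": 1}, expected_response={"B": -1}),  # miss
            TrainingRestriction(stimulus={"B": -1}, expected_response={"A": -1, "C": -1}),  # 2 hits
        ]
        expected = np.mean([1.0, 0.0, 1.0])
        assert restriction_accuracy(weights, restrictions, toy_net) == pytest.approx(expected)

    def test_dead_zone_blocks_tiny_activities(self):
        net = two_node_net()
        weights = {("A", "B"): 0.01}
        restriction = TrainingRestriction(stimulus={"A": 1}, expected_response={"B": 1})
        assert restriction_accuracy(weights, [restriction], net) == 0.0


class TestSampleSolutions:
    def test_trivially_satisfiable_restriction_accepts_quickly(self):
        net = two_node_net()
        restriction = TrainingRestriction(stimulus={"A": 1}, expected_response={"B": 1})
        sols = sample_solutions(net, [restriction], n_accept=2, seed=0, max_draws=20)
        assert len(sols) == 2
        assert all(s.accuracy >= 0.85 for s in sols)

    def test_contradictory_restrictions_infeasible(self):
        net = two_node_net()
        contradictory = [
            TrainingRestriction(stimulus={"A": 1}, expected_response={"B": 1}),
            TrainingRestriction(stimulus={"A": 1}, expected_response={"B": -1}),
        ]
        with pytest.raises(InfeasibleSamplingError, match="infeasible"):
            sample_solutions(
                net, contradictory, n_accept=1, accuracy_min=1.0, seed=0, max_draws=5
            )

    def test_signed_edges_keep_their_sign(self, medium_net):
        eng = PropagationEngine(medium_net)
        rng = np.random.default_rng(0)
        w = eng.random_weights(rng)
        signed = eng.edge_signs != 0
        assert np.all(np.sign(w[signed]) == eng.edge_signs[signed])

    def test_accepted_solutions_respect_accuracy_floor(self):
        spec = SynthSpec(
            n_nodes=150, attachment=2, n_diseases=1, effectors_per_disease=5,
            overlap_with_base=(), base_union_overlap=None, seed=5,
        )
        net = synth_interactome(spec)
        eng = PropagationEngine(net)
        truth = eng.random_weights(np.random.default_rng(2))
        restrictions = synth_restrictions(net, truth, 10, seed=3, engine=eng)
        sols = sample_solutions(net, restrictions, n_accept=3, seed=4, engine=eng)
        assert min(s.accuracy for s in sols) >= 0.85

    def test_same_seed_reproducible(self):
        net = two_node_net()
        restriction = TrainingRestriction(stimulus={"A": 1}, expected_response={"B": 1})
        a = sample_solutions(net, [restriction], n_accept=1, seed=3, max_draws=10)
        b = sample_solutions(net, [restriction], n_accept=1, seed=3, max_draws=10)
        assert a == b


class TestDrugStimulus:
    def make_curve(self, peak):
        times = np.linspace(0, 10, 11)
        conc = peak * np.exp(-0.5 * (times - 3) ** 2)
        return ConcentrationCurve(tissue="brain", times=times, concentrations=conc)

    def test_zero_concentration_gives_zero_magnitudes(self):
        drug = DrugDefinition(drug_id="d", targets={"X": 1, "Y": -1})
        curve = ConcentrationCurve(
            tissue="brain", times=np.linspace(0, 5, 6), concentrations=np.zeros(6)
        )
        stim = drug_stimulus(drug, curve, ec50=1.0)
        assert stim == {"X": 0.0, "Y": 0.0}

    def test_saturation_approaches_effect_signs(self):
        drug = DrugDefinition(drug_id="d", targets={"X": 1, "Y": -1})
        stim = drug_stimulus(drug, self.make_curve(peak=1e6), ec50=1.0)
        assert stim["X"] == pytest.approx(1.0, abs=1e-5)
        assert stim["Y"] == pytest.approx(-1.0, abs=1e-5)

    def test_half_occupancy_at_ec50(self):
        drug = DrugDefinition(drug_id="d", targets={"X": 1})
        curve = self.make_curve(peak=2.0)
        stim = drug_stimulus(drug, curve, ec50=curve.cmax)
        assert stim["X"] == pytest.approx(0.5)

    def test_non_brain_curve_rejected(self):
        drug = DrugDefinition(drug_id="d", targets={"X": 1})
        curve = ConcentrationCurve(
            tissue="liver", times=np.linspace(0, 5, 6), concentrations=np.ones(6)
        )
        with pytest.raises(NetModelError, match="brain"):
            drug_stimulus(drug, curve, ec50=1.0)
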