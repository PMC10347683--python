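"""Reverted-protein calls, tSignal, population consensus and mechanism paths."""

import itertools

import numpy as np
import pytest

from comornet.characterization import DrugDefinition
from comornet.interactome import Edge, Interactome, enumerate_paths
from comornet.moa import (
    MoAError,
    classify_reverted,
    compute_tsignal,
    consensus_reverted,
    extract_mechanism_paths,
    load_reverted_table,
    summarize_reverted_table,
)
from comornet.netmodel import NetworkModelSolution, ProteinActivity
from conftest import make_disease


def activity(**values):
    return ProteinActivity(values={g: float(v) for g, v in values.items()})


class TestClassifyReverted:
    def test_opposite_sign_above_half_is_reverted(self):
        disease = make_disease("d", {"X": 1})
        calls = classify_reverted(activity(X=-0.6), disease)
        assert calls[0].reverted

    def test_boundary_value_is_not_reverted(self):
        disease = make_disease("d", {"X": 1})
        assert not classify_reverted(activity(X=-0.5), disease)[0].reverted

    def test_same_direction_is_not_reverted(self):
        disease = make_disease("d", {"X": 1})
        assert not classify_reverted(activity(X=0.9), disease)[0].reverted

    def test_missing_effectors_get_zero_activity(self):
        disease = make_disease("d", {"X": 1, "Y": -1})
        calls = {c.gene: c for c in classify_reverted(activity(X=-0.9), disease)}
        assert calls["Y"].predicted_activity == 0.0
        assert not calls["Y"].reverted

    def test_threshold_monotonicity(self):
        """The reverted set at a lower threshold contains the set at a higher one."""
        disease = make_disease("d", {g: 1 for g in "ABCDE"})
        act = activity(A=-0.95, B=-0.7, C=-0.55, D=-0.3, E=0.9)
        reverted_at = {
            t: {c.gene for c in classify_reverted(act, disease, threshold=t) if c.reverted}
            for t in (0.3, 0.5, 0.8)
        }
        assert reverted_at[0.8] <= reverted_at[0.5] <= reverted_at[0.3]


class TestTSignal:
    def test_full_reversion_gives_minus_one(self):
        disease = make_disease("d", {"X": 1, "Y": -1})
        assert compute_tsignal(activity(X=-1, Y=1), disease) == pytest.approx(-1.0)

    def test_zero_activities_give_zero(self):
        disease = make_disease("d", {"X": 1, "Y": -1})
        assert compute_tsignal(activity(), disease) == 0.0

    def test_three_effector_arithmetic(self):
        disease = make_disease("d", {"A": 1, "B": 1, "C": 1})
        assert compute_tsignal(activity(A=0.5, B=-1.0, C=0.0), disease) == pytest.approx(-1 / 6)


class TestConsensus:
    def test_published_depression_table_counts(self, depression_table_path):
        frame = load_reverted_table(depression_table_path)
        counts = summarize_reverted_table(frame)
        assert counts["adult"] == 49
        assert counts["pediatric"] == 44
        assert counts["both"] == 44
        assert counts["total"] == 49

    def test_published_bed_table_counts(self, bed_table_path):
        counts = summarize_reverted_table(load_reverted_table(bed_table_path))
        assert counts["total"] == 8
        assert counts["adhd_effectors"] == 4

    def test_cohort_mean_rule(self):
        disease = make_disease("d", {"X": 1})
        adult = [activity(X=-0.9), activity(X=-0.3)]  # mean -0.6 -> reverted
        pediatric = [activity(X=-0.4), activity(X=-0.4)]  # mean -0.4 -> not
        report = consensus_reverted(adult, pediatric, disease)
        assert report.reverted["Adult"] == ("X",)
        assert report.reverted["Pediatric"] == ()
        assert report.reverted["Both"] == ()

    def test_all_zero_cohort_reverts_nothing(self):
        disease = make_disease("d", {"X": 1, "Y": -1})
        zeros = [activity(X=0, Y=0)]
        report = consensus_reverted(zeros, zeros, disease)
        assert report.counts == {"Adult": 0, "Pediatric": 0, "Both": 0}

    def test_counts_invariant_under_patient_reordering(self):
        disease = make_disease("d", {"X": 1, "Y": 1})
        adult = [activity(X=-0.9, Y=0.1), activity(X=-0.8, Y=-0.9), activity(X=-0.2, Y=-0.6)]
        pediatric = [activity(X=-0.6, Y=-0.6), activity(X=-0.7, Y=0.2)]
        baseline = consensus_reverted(adult, pediatric, disease).counts
        for perm in itertools.permutations(adult):
            assert consensus_reverted(list(perm), pediatric, disease).counts == baseline

    def test_majority_rule_option(self):
        disease = make_disease("d", {"X": 1})
        adult = [activity(X=-0.9), activity(X=-0.9), activity(X=0.9)]
        pediatric = [activity(X=-0.9)]
        report = consensus_reverted(adult, pediatric, disease, rule="majority")
        assert report.reverted["Adult"] == ("X",)

    def test_empty_cohort_raises(self):
        disease = make_disease("d", {"X": 1})
        with pytest.raises(MoAError):
            consensus_reverted([], [activity(X=0)], disease)


def hand_mechanism_system():
    """7-node system with hand-set weights for path filtering.

    Drug target T (effect +1); disease effectors E1 (sign +1) and E2 (sign -1).
    Net: T-A-E1 (positive weights), T-B-E2, T-C, C-E1 (negative weight on C-E1).
    """
    net = Interactome(
        edges=[
            Edge("T", "A"), Edge("A", "E1"),
            Edge("T", "B"), Edge("B", "E2"),
            Edge("T", "C"), Edge("C", "E1"),
        ]
    )
    drug = DrugDefinition(drug_id="drug", targets={"T": 1})
    disease = make_disease("d", {"E1": 1, "E2": -1})
    weights = {
        ("A", "E1"): 0.9, ("T", "A"): -0.9,   # product -1: consistent with E1 reverted (a<0)
        ("B", "E2"): 0.8, ("T", "B"): 0.8,    # product +1: consistent with E2 activated (a>0)
        ("C", "T"): 0.7, ("C", "E1"): 0.7,    # product +1: inconsistent with E1 a<0
    }
    solution = NetworkModelSolution(edge_weights=weights, n_steps=3, accuracy=1.0, seed=0)
    act = activity(E1=-0.9, E2=0.85, T=1.0)
    return net, drug, disease, solution, act


class TestMechanismPaths:
    def test_hand_built_system_matches_manual_filter(self):
        net, drug, disease, solution, act = hand_mechanism_system()
        paths = extract_mechanism_paths([solution] * 3, [act] * 3, drug, disease, net)
        got = {p.nodes for p in paths}
        # manual filter: T-A-E1 consistent, T-B-E2 consistent, T-C-E1 not
        assert ("T", "A", "E1") in got
        assert ("T", "B", "E2") in got
        assert ("T", "C", "E1") not in got
        assert all(p.frequency == 1.0 for p in paths)

    def test_partial_frequency_excluded_at_full_requirement(self):
        net, drug, disease, solution, act = hand_mechanism_system()
        weak = activity(E1=-0.3, E2=0.1)  # this patient does not qualify
        paths = extract_mechanism_paths(
            [solution] * 10, [act] * 9 + [weak], drug, disease, net, frequency_min=1.0
        )
        assert paths == []
        relaxed = extract_mechanism_paths(
            [solution] * 10, [act] * 9 + [weak], drug, disease, net, frequency_min=0.9
        )
        assert relaxed

    def test_boundary_activation_excluded(self):
        net, drug, disease, solution, _ = hand_mechanism_system()
        at_boundary = activity(E1=-0.8, E2=0.8)
        paths = extract_mechanism_paths(
            [solution], [at_boundary], drug, disease, net, activation_min=0.8
        )
        assert paths == []

    def test_zero_weight_edge_breaks_path(self):
        net, drug, disease, solution, act = hand_mechanism_system()
        weights = dict(solution.edge_weights)
        weights[("A", "E1")] = 0.0
        broken = NetworkModelSolution(edge_weights=weights, n_steps=3, accuracy=1.0, seed=0)
        paths = extract_mechanism_paths([broken], [act], drug, disease, net)
        assert ("T", "A", "E1") not in {p.nodes for p in paths}

    def test_paths_contained_in_enumeration(self):
        net, drug, disease, solution, act = hand_mechanism_system()
        paths = extract_mechanism_paths([solution], [act], drug, disease, net)
        universe = {tuple(p) for p in enumerate_paths(net, {"T"}, {"E1", "E2"}, max_edges=3)}
        assert {p.nodes for p in paths} <= universe

    def test_no_solutions_raises(self):
        net, drug, disease, _, _ = hand_mechanism_system()
        with pytest.raises(MoAError):
            extract_mechanism_paths([], [], drug, disease, net)
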