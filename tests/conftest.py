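import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

from comornet.characterization import DiseaseCharacterization, DrugDefinition, EffectorProtein
from comornet.interactome import Edge, Interactome
from comornet.synthetic import SynthSpec, fixture_path, synth_interactome


def make_disease(disease_id, signed_genes, motive="m1"):
    """Characterization from {gene: sign}; single shared motive."""
    return DiseaseCharacterization(
        disease_id=disease_id,
        motives=(motive,),
        effectors=frozenset(
            EffectorProtein(gene=g, sign=s, motives=frozenset({motive}))
            for g, s in signed_genes.items()
        ),
    )


@pytest.fixture
def chain_net():
    """A -> B -> C -> D directed chain."""
    return Interactome(
        edges=[
            Edge("A", "B", directed=True),
            Edge("B", "C", directed=True),
            Edge("C", "D", directed=True),
        ]
    )


@pytest.fixture
def toy_net():
    """Small mixed undirected net used across modules.

        A - B - C - D
            |       |
            E ------+
        F isolated-ish: F - A
    """
    return Interactome(
        edges=[
            Edge("A", "B"),
            Edge("B", "C"),
            Edge("C", "D"),
            Edge("B", "E"),
            Edge("E", "D"),
            Edge("F", "A"),
        ]
    )


@pytest.fixture(scope="session")
def medium_net():
    """Seeded 300-node scale-free net for scoring/propagation tests."""
    spec = SynthSpec(
        n_nodes=300,
        attachment=3,
        n_diseases=2,
        effectors_per_disease=30,
        overlap_with_base=(0.2,),
        base_union_overlap=None,
        seed=1234,
    )
    return synth_interactome(spec)


@pytest.fixture(scope="session")
def ldx_targets_path():
    return fixture_path("ldx_targets.tsv")


@pytest.fixture(scope="session")
def bed_table_path():
    return fixture_path("bed_reverted.tsv")


@pytest.fixture(scope="session")
def depression_table_path():
    return fixture_path("depression_reverted.tsv")


@pytest.fixture(scope="session")
def bed_characterization_path():
    return fixture_path("bed_characterization_synthetic.tsv")
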