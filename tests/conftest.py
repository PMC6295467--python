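import numpy as np
import pytest

from mdaskf import generate_synthetic_dataset
from mdaskf.io import DiseaseOntology


@pytest.fixture(scope="session")
def synthetic():
    """Default-parameter planted dataset used across modules (seed 7)."""
    return generate_synthetic_dataset(seed=7)


@pytest.fixture(scope="session")
def dataset(synthetic):
    return synthetic.as_dataset()


@pytest.fixture
def chain_ontology():
    """root -> a -> d, with diseases mapped to d and to a."""
    return DiseaseOntology(
        nodes={"root", "a", "d"},
        parent_links={"d": {"a"}, "a": {"root"}},
        disease_to_terms={"D": {"d"}, "A": {"a"}},
    )


@pytest.fixture
def sibling_ontology():
    """Two sibling terms under one root."""
    return DiseaseOntology(
        nodes={"root", "t1", "t2"},
        parent_links={"t1": {"root"}, "t2": {"root"}},
        disease_to_terms={"D1": {"t1"}, "D2": {"t2"}},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
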