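import numpy as np
import pytest

from gosubset.ontology import OntologyGraph
from gosubset import synthetic as sy


@pytest.fixture
def chain_graph():
    """A <- B <- C is_a chain rooted at A."""
    return OntologyGraph(
        terms={"A", "B", "C"},
        edges={("B", "A", "is_a"), ("C", "B", "is_a")},
        root="A",
        namespaces={t: "molecular_function" for t in "ABC"},
    )


@pytest.fixture
def diamond_graph():
    """A <- {B, C} <- D."""
    return OntologyGraph(
        terms={"A", "B", "C", "D"},
        edges={("B", "A", "is_a"), ("C", "A", "is_a"), ("D", "B", "is_a"), ("D", "C", "is_a")},
        root="A",
    )


def random_dag(rng: np.random.Generator, n_terms: int = 50, p_edge: float = 0.15) -> OntologyGraph:
    """Random rooted DAG: term i may point to any lower-index term as parent."""
    terms = [f"T{i}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        parents = [j for j in range(i) if rng.random() < p_edge] or [int(rng.integers(i))]
        for j in parents:
            edges.add((terms[i], terms[j], "is_a"))
    return OntologyGraph(terms=set(terms), edges=edges, root="T0",
                         namespaces={t: "molecular_function" for t in terms})


@pytest.fixture(scope="session")
def synth_world():
    """Default stated world: 4 leaves x 40 proteins, delta=6, tree(2)."""
    spec = sy.SynthSpec(seed=1, seq_length=120)
    g = sy.make_ontology(spec)
    table, memberships = sy.make_annotations(spec, g)
    feats = sy.make_features(spec, memberships)
    return spec, g, table, memberships, feats
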