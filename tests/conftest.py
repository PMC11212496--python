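import numpy as np
import pytest

from complexmod import ComplexGraph, PlantedSpec, generate_planted_structure, parse_structure
from complexmod.fixtures import chain_labels


@pytest.fixture(scope="session")
def barbell_graph() -> ComplexGraph:
    """Two unit-weight 3-cliques joined by one bridge edge."""
    edges = {
        ("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1,
        ("d", "e"): 1, ("d", "f"): 1, ("e", "f"): 1,
        ("c", "d"): 1,
    }
    return ComplexGraph(vertices=tuple("abcdef"), edges=edges)


@pytest.fixture(scope="session")
def two_pair_graph() -> ComplexGraph:
    """Two disjoint unit-weight edges: a-b and c-d."""
    return ComplexGraph(vertices=("a", "b", "c", "d"), edges={("a", "b"): 1, ("c", "d"): 1})


@pytest.fixture()
def planted_structure(tmp_path):
    """2 modules x 3 chains x 20 residues, default geometry; parsed + truth."""
    spec = PlantedSpec(n_modules=2, chains_per_module=3, residues_per_chain=20, seed=11)
    planted = generate_planted_structure(spec, tmp_path / "planted.cif")
    return parse_structure(planted.path), planted


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.5, w_max: int = 10) -> ComplexGraph:
    """Erdős–Rényi-style random integer-weighted graph on chain-like labels."""
    labels = chain_labels(n)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges[(labels[i], labels[j])] = int(rng.integers(1, w_max + 1))
    return ComplexGraph(vertices=tuple(labels), edges=edges)
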