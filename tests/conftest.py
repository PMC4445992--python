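import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dcafp.io import CATEGORIES, AnnotationSet, PPINetwork
from dcafp.similarity import SimilarityBundle, build_similarity_bundle
from dcafp.synthetic import worked_fixture


def random_network(rng: np.random.Generator, n: int, p: float = 0.3) -> PPINetwork:
    """Erdős–Rényi network on n proteins named n0..n{n-1}."""
    pairs = [
        (f"n{i}", f"n{j}")
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PPINetwork.from_edge_ids(pairs, extra_proteins=[f"n{i}" for i in range(n)])


def random_annotations(
    rng: np.random.Generator, network: PPINetwork, n_terms: int = 6, max_per: int = 3
) -> AnnotationSet:
    ann = AnnotationSet.empty(network.n_V)
    for m in CATEGORIES:
        for i in range(network.n_V):
            k = int(rng.integers(0, max_per + 1))
            ann.terms[m][i] = {
                f"{m}{int(t)}" for t in rng.integers(0, n_terms, size=k)
            }
    return ann


def random_instance(
    rng: np.random.Generator, n: int, p: float = 0.4
) -> tuple[PPINetwork, SimilarityBundle, np.ndarray, np.ndarray]:
    """Random (network, similarity bundle, feasible W, feasible R)."""
    net = random_network(rng, n, p)
    sims = build_similarity_bundle(net, random_annotations(rng, net))
    W = rng.uniform(0, 1, size=(n, n))
    np.fill_diagonal(W, 0.0)
    R = rng.uniform(0, 1, size=(n, 3))
    R /= R.sum(axis=1, keepdims=True)
    return net, sims, W, R


@pytest.fixture(scope="session")
def fixture_instance():
    """The deterministic 12-protein two-complex instance."""
    return worked_fixture()
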