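"""Pairwise similarity matrices feeding the clustering objective.

Two kinds of evidence are summarized as symmetric matrices with entries in
[0, 1] and zero diagonals:

* **functional** — for each GO aspect m ∈ {p, f, c}, ``A_m[i, j]`` is the
  Jaccard index of the term sets of proteins i and j in that aspect;
* **topological** — ``D[i, j]`` is the Jaccard index of the open
  neighborhoods N(i) and N(j), i.e. the fraction of interaction partners the
  two proteins share.

Open neighborhoods exclude the protein itself, so two adjacent proteins with
no common third partner score 0. The Jaccard index of two empty sets is
defined as 0: two unannotated (or isolated) proteins carry no evidence of
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CATEGORIES, AnnotationSet, PPINetwork


@dataclass
class SimilarityBundle:
    """The three functional similarity matrices and the topological one."""

    A_p: np.ndarray
    A_f: np.ndarray
    A_c: np.ndarray
    D: np.ndarray

    def functional(self, category: str) -> np.ndarray:
        return {"p": self.A_p, "f": self.A_f, "c": self.A_c}[category]

    @property
    def functional_stack(self) -> np.ndarray:
        """Shape (3, n_V, n_V) array in the fixed (p, f, c) order."""
        return np.stack([self.A_p, self.A_f, self.A_c])

    @property
    def n_V(self) -> int:
        return self.D.shape[0]


def jaccard(set_a: set, set_b: set) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty."""
    if not set_a and not set_b:
        return 0.0
    inter = len(set_a & set_b)
    if inter == 0:
        return 0.0
    return inter / (len(set_a) + len(set_b) - inter)


def _pairwise_jaccard(sets: list[set]) -> np.ndarray:
    n = len(sets)
    M = np.zeros((n, n))
    for i in range(n):
        si = sets[i]
        if not si:
            continue
        for j in range(i + 1, n):
            score = jaccard(si, sets[j])
            M[i, j] = M[j, i] = score
    return M


def build_functional_similarity(
    network: PPINetwork, annotations: AnnotationSet, category: str
) -> np.ndarray:
    """A_m with ``a_ij^m = jaccard(terms_i^m, terms_j^m)``, zero diagonal."""
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}")
    if annotations.n_proteins != network.n_V:
        raise ValueError("annotations are not indexed against this network")
    return _pairwise_jaccard(annotations.term_sets(category))


def build_topological_similarity(network: PPINetwork) -> np.ndarray:
    """D with ``d_ij = jaccard(N(i), N(j))`` over open neighborhoods."""
    return _pairwise_jaccard(network.neighbor_sets())


def build_similarity_bundle(
    network: PPINetwork, annotations: AnnotationSet
) -> SimilarityBundle:
    return SimilarityBundle(
        A_p=build_functional_similarity(network, annotations, "p"),
        A_f=build_functional_similarity(network, annotations, "f"),
        A_c=build_functional_similarity(network, annotations, "c"),
        D=build_topological_similarity(network),
    )
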