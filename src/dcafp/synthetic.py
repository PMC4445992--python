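"""Synthetic benchmarks with planted complexes and category-coherent
annotations.

The generator emulates the two structural assumptions the method relies on:
planted complexes are dense (within-complex edge probability ``p_in``) on a
sparse background (``p_out``), and each complex's members share coherent
functional terms only in that complex's *preferred* subset of the three GO
aspects. Coherent term blocks are disjoint across complexes and categories,
and noise terms come from a separate large pool, so planted preference
recovery is unambiguous and the block structure of the functional
similarity matrices is analyzable.

Proteins shared between overlapping complexes inherit the union of their
complexes' coherent terms and preferred categories, mirroring multi-complex
membership in real annotation data. No attempt is made to mimic real degree
distributions or the GO DAG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CATEGORIES,
    AnnotationSet,
    ClusterSet,
    PPINetwork,
    write_complexes,
    write_network,
)

#: default preferred-category subsets, cycled over complexes
_DEFAULT_PREFS: tuple[tuple[str, ...], ...] = (
    ("p", "c"),
    ("f",),
    ("p",),
    ("f", "c"),
    ("c",),
)

_NOISE_POOL = 1000  # noise terms per category


@dataclass
class SynthConfig:
    """Study conditions for one benchmark instance.

    Defaults plant five complexes of eight proteins with one pair sharing
    two proteins on a 30-protein background, near-clique inside (p_in=0.9)
    and sparse elsewhere (p_out=0.02), three coherent terms per preferred
    category and one random noise term per protein and category.
    """

    n_background: int = 30
    complex_sizes: tuple[int, ...] = (8, 8, 8, 8, 8)
    overlap_spec: tuple[tuple[tuple[int, int], int], ...] = (((0, 1), 2),)
    p_in: float = 0.9
    p_out: float = 0.02
    preferred_categories: tuple[tuple[str, ...], ...] | None = None
    terms_per_complex: int = 3
    noise_terms: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if any(s < 2 for s in self.complex_sizes):
            raise ValueError("complex sizes must be >= 2")
        n_c = len(self.complex_sizes)
        for (a, b), shared in self.overlap_spec:
            if not (0 <= a < n_c and 0 <= b < n_c) or a == b:
                raise ValueError(f"overlap pair ({a},{b}) is invalid")
            if shared >= self.complex_sizes[a] or shared >= self.complex_sizes[b]:
                raise ValueError("shared count must be smaller than both complexes")
        if self.preferred_categories is None:
            self.preferred_categories = tuple(
                _DEFAULT_PREFS[k % len(_DEFAULT_PREFS)] for k in range(n_c)
            )
        if len(self.preferred_categories) != n_c:
            raise ValueError("need one preferred-category subset per complex")
        for prefs in self.preferred_categories:
            if not prefs or any(m not in CATEGORIES for m in prefs):
                raise ValueError(f"invalid preferred categories {prefs}")


@dataclass
class SyntheticInstance:
    network: PPINetwork
    annotations: AnnotationSet
    ground_truth: ClusterSet
    preference_truth: dict[str, frozenset[str]]
    config: SynthConfig = field(repr=False)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write edges.tsv / annotations.tsv / complexes.txt / truth.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": directory / "edges.tsv",
            "annotations": directory / "annotations.tsv",
            "complexes": directory / "complexes.txt",
            "truth": directory / "truth.json",
        }
        write_network(self.network, paths["network"])
        with open(paths["annotations"], "w") as fh:
            for m in CATEGORIES:
                for i, terms in enumerate(self.annotations.term_sets(m)):
                    for term in sorted(terms):
                        fh.write(
                            f"{self.network.proteins[i]}\t{m.upper()}\t{term}\n"
                        )
        write_complexes(self.ground_truth, paths["complexes"])
        truth = {
            "preferred_categories": {
                p: sorted(cats) for p, cats in sorted(self.preference_truth.items())
            },
            "complexes": [sorted(c) for c in self.ground_truth],
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _plant_memberships(config: SynthConfig) -> list[list[str]]:
    """Assign protein identifiers to complexes, honoring the overlap spec by
    reusing the tail members of the earlier complex of each pair."""
    shared_into: dict[int, list[tuple[int, int]]] = {}
    for (a, b), count in config.overlap_spec:
        lo, hi = min(a, b), max(a, b)
        shared_into.setdefault(hi, []).append((lo, count))
    counter = 0
    members: list[list[str]] = []
    for k, size in enumerate(config.complex_sizes):
        mem: list[str] = []
        for lo, count in shared_into.get(k, []):
            borrowed = [p for p in members[lo][-count:] if p not in mem]
            mem.extend(borrowed)
        if len(mem) > size:
            raise ValueError(f"overlap spec infeasible for complex {k}")
        while len(mem) < size:
            mem.append(f"P{counter:04d}")
            counter += 1
        members.append(mem)
    return members


def generate(config: SynthConfig) -> SyntheticInstance:
    """Draw one benchmark instance; a fixed seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    members = _plant_memberships(config)
    planted: list[str] = []
    seen: set[str] = set()
    for mem in members:
        for p in mem:
            if p not in seen:
                seen.add(p)
                planted.append(p)
    background = [f"B{k:04d}" for k in range(config.n_background)]
    proteins = planted + background
    complex_of: dict[str, set[int]] = {p: set() for p in proteins}
    for k, mem in enumerate(members):
        for p in mem:
            complex_of[p].add(k)

    n = len(proteins)
    edges: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteins[i], proteins[j]
            within = bool(complex_of[a] & complex_of[b])
            p_edge = config.p_in if within else config.p_out
            if rng.random() < p_edge:
                edges.append((a, b))
    index = {p: i for i, p in enumerate(proteins)}
    network = PPINetwork(
        proteins=proteins, edges={(index[a], index[b]) for a, b in edges}
    )

    annotations = AnnotationSet.empty(n)
    for k, mem in enumerate(members):
        coherent = {
            m: {f"go:{k}:{m}:{t}" for t in range(config.terms_per_complex)}
            for m in config.preferred_categories[k]
        }
        for p in mem:
            i = network.index[p]
            for m, terms in coherent.items():
                annotations.terms[m][i] |= terms
    if config.noise_terms:
        for m in CATEGORIES:
            draws = rng.integers(0, _NOISE_POOL, size=(n, config.noise_terms))
            for i in range(n):
                annotations.terms[m][i] |= {
                    f"noise:{m}:{int(t)}" for t in draws[i]
                }

    ground_truth = ClusterSet(
        clusters=[frozenset(mem) for mem in members], provenance="reference"
    )
    preference_truth = {
        p: frozenset(
            m for k in complex_of[p] for m in config.preferred_categories[k]
        )
        for p in proteins
    }
    return SyntheticInstance(
        network=network,
        annotations=annotations,
        ground_truth=ground_truth,
        preference_truth=preference_truth,
        config=config,
    )


def worked_fixture() -> SyntheticInstance:
    """Deterministic 12-protein instance used across the test suite and docs:
    two overlapping planted complexes (6 + 6 sharing 2 proteins), preferring
    categories {p, c} and {f} respectively, plus 2 background proteins."""
    config = SynthConfig(
        n_background=2,
        complex_sizes=(6, 6),
        overlap_spec=(((0, 1), 2),),
        p_in=1.0,
        p_out=0.05,
        preferred_categories=(("p", "c"), ("f",)),
        terms_per_complex=3,
        noise_terms=1,
        seed=20240,
    )
    return generate(config)
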