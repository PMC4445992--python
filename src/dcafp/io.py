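"""Readers and writers for PPI edge lists, functional-annotation tables and
protein-complex catalogs.

All on-disk formats are plain text:

* **edge list** — one interaction per line, first two whitespace-separated
  tokens are the protein identifiers, extra columns ignored, ``#`` comments
  allowed (covers DIP/BioGRID tab exports);
* **annotation table** — three tab-separated columns
  ``protein<TAB>category<TAB>term`` with category codes ``P``/``F``/``C``
  (biological process, molecular function, cellular component), or a GAF 2.x
  subset via :func:`read_annotations_gaf`;
* **complex catalog** — one complex per line, whitespace-separated protein
  identifiers (MIPS/CYC2008 convention).

Protein identifiers are opaque case-sensitive strings; no symbol mapping is
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: the three Gene Ontology aspects, in the fixed column order used by the
#: preference matrix R: biological process, molecular function, cellular
#: component.
CATEGORIES: tuple[str, str, str] = ("p", "f", "c")

_CATEGORY_CODES = {"p": "p", "f": "f", "c": "c", "P": "p", "F": "f", "C": "c"}


@dataclass
class PPINetwork:
    """An undirected protein–protein interaction network.

    Proteins are indexed 0..n_V−1 in first-appearance order; edges are stored
    as unordered index pairs ``(i, j)`` with ``i < j``. Self-loops and
    duplicate edges are never stored.
    """

    proteins: list[str]
    edges: set[tuple[int, int]]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {p: i for i, p in enumerate(self.proteins)}
        if len(self.index) != len(self.proteins):
            raise ValueError("duplicate protein identifiers")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop stored for index {i}")
            if i > j:
                raise ValueError("edge indices must satisfy i < j")

    @property
    def n_V(self) -> int:
        return len(self.proteins)

    @property
    def n_E(self) -> int:
        return len(self.edges)

    @property
    def T(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency indicator with zero diagonal."""
        T = np.zeros((self.n_V, self.n_V))
        for i, j in self.edges:
            T[i, j] = T[j, i] = 1.0
        return T

    def neighbors(self, i: int) -> set[int]:
        """Open neighborhood of protein ``i`` (the protein itself excluded)."""
        out = set()
        for a, b in self.edges:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def neighbor_sets(self) -> list[set[int]]:
        """Open neighborhoods of every protein, in index order."""
        out: list[set[int]] = [set() for _ in range(self.n_V)]
        for a, b in self.edges:
            out[a].add(b)
            out[b].add(a)
        return out

    @classmethod
    def from_edge_ids(
        cls, pairs: Iterable[tuple[str, str]], extra_proteins: Iterable[str] = ()
    ) -> "PPINetwork":
        """Build a network from identifier pairs, dropping self-loops and
        duplicates; protein order is first-appearance order."""
        proteins: list[str] = []
        index: dict[str, int] = {}

        def idx(p: str) -> int:
            if p not in index:
                index[p] = len(proteins)
                proteins.append(p)
            return index[p]

        edges: set[tuple[int, int]] = set()
        for a, b in pairs:
            ia, ib = idx(a), idx(b)
            if ia == ib:
                continue
            edges.add((min(ia, ib), max(ia, ib)))
        for p in extra_proteins:
            idx(p)
        return cls(proteins=proteins, edges=edges)


@dataclass
class AnnotationSet:
    """Per-protein functional term sets in the three GO aspects.

    ``terms[m][i]`` is the (possibly empty) set of terms of category
    ``m ∈ {"p","f","c"}`` attached to the protein with network index ``i``.
    """

    terms: dict[str, list[set[str]]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.terms.values()}
        if set(self.terms) != set(CATEGORIES):
            raise ValueError(f"categories must be exactly {CATEGORIES}")
        if len(lengths) != 1:
            raise ValueError("categories index different numbers of proteins")

    @property
    def n_proteins(self) -> int:
        return len(self.terms["p"])

    def term_sets(self, category: str) -> list[set[str]]:
        return self.terms[category]

    @classmethod
    def empty(cls, n_proteins: int) -> "AnnotationSet":
        return cls({m: [set() for _ in range(n_proteins)] for m in CATEGORIES})


@dataclass
class ClusterSet:
    """A family of protein-ID sets (base clusters, predictions or a reference
    catalog). Identical sets are stored once; insertion order is preserved."""

    clusters: list[frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        unique: list[frozenset[str]] = []
        for c in self.clusters:
            fc = frozenset(c)
            if not fc:
                raise ValueError("empty cluster")
            if fc not in seen:
                seen.add(fc)
                unique.append(fc)
        self.clusters = unique

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def as_family(self) -> frozenset[frozenset[str]]:
        return frozenset(self.clusters)


# ---------------------------------------------------------------------------
# networks


def read_network(path: str | Path) -> PPINetwork:
    """Read an edge list, removing self-loops and duplicate interactions.

    Raises ``ValueError`` naming the line number on malformed lines (fewer
    than two tokens) and on files that yield no valid edge.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected at least "
                    f"two columns, got {len(tokens)}"
                )
            pairs.append((tokens[0], tokens[1]))
    net = PPINetwork.from_edge_ids(pairs)
    if net.n_E == 0:
        raise ValueError(f"{path}: empty network (no valid edges)")
    return net


def write_network(network: PPINetwork, path: str | Path) -> None:
    """Write the edge list, one interaction per line, tab-separated."""
    with open(path, "w") as fh:
        for i, j in sorted(network.edges):
            fh.write(f"{network.proteins[i]}\t{network.proteins[j]}\n")


# ---------------------------------------------------------------------------
# annotations


def _assemble_annotations(
    rows: Iterable[tuple[str, str, str]],
    network: PPINetwork,
    blacklist: set[str] | None,
) -> AnnotationSet:
    blacklist = blacklist or set()
    ann = AnnotationSet.empty(network.n_V)
    seen_any = False
    for protein, code, term in rows:
        if code not in _CATEGORY_CODES:
            raise ValueError(f"unknown category code {code!r}")
        i = network.index.get(protein)
        if i is None:
            continue  # protein absent from the network: no index allocated
        seen_any = True
        if term in blacklist:
            continue
        ann.terms[_CATEGORY_CODES[code]][i].add(term)
    if not seen_any:
        warnings.warn(
            "annotation table shares no protein with the network", stacklevel=3
        )
    return ann


def read_annotations(
    path: str | Path,
    network: PPINetwork,
    blacklist: Iterable[str] | None = None,
) -> AnnotationSet:
    """Read a 3-column table ``protein  P|F|C  term`` (tab-separated).

    Annotations are restricted to proteins present in ``network``; terms in
    ``blacklist`` are dropped (the paper-style exclusion of uninformative
    cellular-component terms is supplied by the caller, never hard-coded).
    Proteins absent from the table end up with empty sets.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        names=["protein", "category", "term"], skip_blank_lines=True,
    )
    if df.shape[1] < 3 or df["term"].isna().any():
        raise ValueError(f"{path}: expected 3 tab-separated columns")
    rows = zip(df["protein"], df["category"], df["term"])
    return _assemble_annotations(rows, network, set(blacklist or ()))


def read_annotations_gaf(
    path: str | Path,
    network: PPINetwork,
    blacklist: Iterable[str] | None = None,
    id_field: str = "id",
) -> AnnotationSet:
    """Thin GAF 2.x adapter: maps aspect codes P/F/C, ignores qualifiers and
    evidence codes. ``id_field`` selects column 2 (``"id"``, DB object ID) or
    column 3 (``"symbol"``) as the protein identifier."""
    col = {"id": 1, "symbol": 2}[id_field]
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            rows.append((fields[col], fields[8], fields[4]))
    return _assemble_annotations(rows, network, set(blacklist or ()))


def read_blacklist(path: str | Path) -> set[str]:
    """One excluded term per line; blank lines and ``#`` comments skipped."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s)
    return out


# ---------------------------------------------------------------------------
# complex catalogs


def read_complexes(path: str | Path, provenance: str = "reference") -> ClusterSet:
    """Read one complex per line (whitespace-separated protein IDs).

    Blank lines are skipped; single-protein lines are kept — size filtering
    is the caller's decision. Duplicate lines collapse to one cluster.
    """
    clusters: list[frozenset[str]] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            clusters.append(frozenset(stripped.split()))
    return ClusterSet(clusters=clusters, provenance=provenance)


def write_complexes(clusters: ClusterSet | Sequence[frozenset[str]], path: str | Path) -> None:
    """Write one complex per line with members sorted, tab-separated."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write("\t".join(sorted(c)) + "\n")


def write_matrix_tsv(
    matrix: np.ndarray, proteins: Sequence[str], path: str | Path
) -> None:
    """Diagnostic dump of a dense square matrix with an ID header row/column."""
    df = pd.DataFrame(matrix, index=list(proteins), columns=list(proteins))
    df.to_csv(path, sep="\t")
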