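"""Molecular graphs and degree-pair edge partitions.

A molecule is modelled as a finite, simple, connected graph on its heavy
(hydrogen-suppressed) atoms: vertices are atoms, edges are bonds, and the
only structural information retained is vertex degree.  The degree-pair
edge partition — the multiset of (d_u, d_v) pairs over all edges uv — is
the sufficient statistic for every degree-based topological index handled
by this package.

Hydrogen convention is the caller's responsibility: the reader never adds
or removes atoms, it validates whatever graph it is given.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "read_graph",
    "from_edges",
    "from_smiles",
    "degree_of",
    "edge_partition",
]


class GraphValidationError(ValueError):
    """Raised when an input fails the simple-connected-graph contract."""


@dataclass(frozen=True)
class MolecularGraph:
    """A validated finite, simple, connected graph.

    Vertex identifiers are opaque strings; no ordering semantics are
    attached to them.  Instances are produced by :func:`from_edges`,
    :func:`read_graph` or :func:`from_smiles` — construct through those so
    the invariants are checked.
    """

    graph: nx.Graph

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class EdgePartition:
    """Counts of edges by ordered degree pair (i, j), i <= j.

    ``counts[(i, j)]`` is m_ij, the number of edges joining a degree-i
    vertex to a degree-j vertex.  The counts always sum to |E|.
    """

    counts: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        for (i, j), m in self.counts.items():
            if not (1 <= i <= j):
                raise GraphValidationError(
                    f"degree pair ({i}, {j}) violates 1 <= i <= j"
                )
            if m <= 0 or m != int(m):
                raise GraphValidationError(
                    f"edge count m_({i},{j}) = {m} is not a positive integer"
                )

    @property
    def n_edges(self) -> int:
        return sum(self.counts.values())


def from_edges(edges: Iterable[tuple[str, str]]) -> MolecularGraph:
    """Build a validated MolecularGraph from (u, v) pairs.

    Rejects self-loops, duplicate edges and disconnected graphs with a
    message naming the offending edge or component.
    """
    g = nx.Graph()
    seen: set[frozenset[str]] = set()
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            raise GraphValidationError(f"self-loop on vertex {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
        seen.add(key)
        g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise GraphValidationError("graph has no vertices (empty edge list)")
    if not nx.is_connected(g):
        comp = min(nx.connected_components(g), key=len)
        raise GraphValidationError(
            f"graph is disconnected; smallest component: {sorted(comp)}"
        )
    # handshake lemma sanity check on every ingested graph
    assert sum(d for _, d in g.degree) == 2 * g.number_of_edges()
    return MolecularGraph(g)


def read_graph(source: str | Path) -> MolecularGraph:
    """Read a molecular graph from an edge-list or JSON file/text.

    Edge-list format: one edge per line, two whitespace-separated vertex
    tokens; ``#`` starts a comment.  JSON alternative:
    ``{"edges": [["a", "b"], ...]}``.  A ``Path`` is read from disk;
    a plain string is parsed directly.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = source
    stripped = text.lstrip()
    if stripped.startswith("{"):
        doc = json.loads(text)
        if "edges" not in doc:
            raise GraphValidationError('JSON graph document lacks an "edges" key')
        return from_edges((str(u), str(v)) for u, v in doc["edges"])
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphValidationError(
                f"line {lineno}: expected two vertex tokens, got {len(parts)}"
            )
        edges.append((parts[0], parts[1]))
    return from_edges(edges)


def from_smiles(smiles: str) -> MolecularGraph:
    """Heavy-atom skeleton of a SMILES string (optional rdkit adapter)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SMILES ingestion requires the optional rdkit extra") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphValidationError(f"could not parse SMILES {smiles!r}")
    edges = [
        (str(b.GetBeginAtomIdx()), str(b.GetEndAtomIdx())) for b in mol.GetBonds()
    ]
    return from_edges(edges)


def degree_of(g: MolecularGraph, u: str) -> int:
    """Number of neighbours of vertex ``u``."""
    if u not in g.graph:
        raise KeyError(f"unknown vertex {u!r}")
    return g.graph.degree[u]


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Tally every edge uv into its degree pair (min(d_u,d_v), max(d_u,d_v))."""
    deg = g.graph.degree
    counts: Counter[tuple[int, int]] = Counter()
    for u, v in g.graph.edges:
        i, j = sorted((deg[u], deg[v]))
        counts[(i, j)] += 1
    part = EdgePartition(dict(counts))
    assert part.n_edges == g.n_edges
    return part
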