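"""Graph data model and readers for the formats the pipeline consumes.

The whole pipeline runs on simple undirected labelled graphs: the
interactome, the per-pathway topologies, and the derived combined
networks.  :class:`NetworkGraph` is a thin validated wrapper around a
:class:`networkx.Graph` that enforces simplicity (no self-loops, no
parallel edges) and caches the all-pairs hop-distance matrix, which the
disease-separation statistics query heavily.

Gene and pathway memberships travel as :class:`GeneSet` objects; gene
symbols are uppercased and whitespace-stripped on ingest so that sets
drawn from different sources match by symbol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkGraph",
    "GeneSet",
    "SetCategory",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "shortest_path_lengths",
]


class GraphFormatError(ValueError):
    """Raised for malformed edge-list / GMT input."""


class SetCategory(str, Enum):
    disease = "disease"
    pathway = "pathway"
    drug_pathway = "drug_pathway"


class NetworkGraph:
    """A simple undirected labelled graph.

    Parameters
    ----------
    edges
        Iterable of (u, v) label pairs.  Self-loops are dropped and
        duplicate / reversed-duplicate edges collapsed.
    nodes
        Optional extra isolated nodes.
    name
        Graph name used in reports.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        name: str = "",
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        n_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.info("dropped %d self-loop(s) while building %r", n_loops, name)
        self._g = g
        self.name = name
        self._dist_cache: tuple[list[str], dict[str, int], np.ndarray] | None = None

    # -- basic container protocol -------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def to_networkx(self) -> nx.Graph:
        """Return the underlying networkx graph (a live view; do not mutate)."""
        return self._g

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "") -> "NetworkGraph":
        out = cls(name=name)
        h = nx.Graph()
        h.add_nodes_from(str(n) for n in g.nodes)
        h.add_edges_from((str(u), str(v)) for u, v in g.edges if u != v)
        out._g = h
        return out

    def subgraph(self, nodes: Iterable[str], name: str = "") -> "NetworkGraph":
        return NetworkGraph.from_networkx(self._g.subgraph(nodes).copy(), name=name)

    def largest_component(self) -> "NetworkGraph":
        if self.n_nodes == 0:
            return self
        comp = max(nx.connected_components(self._g), key=lambda c: (len(c), sorted(c)))
        return self.subgraph(comp, name=self.name)

    def diameter(self) -> int:
        """Hop diameter of the largest connected component."""
        g = self._g
        if g.number_of_nodes() <= 1:
            return 0
        if not nx.is_connected(g):
            logger.warning("graph %r disconnected; diameter on largest component", self.name)
            g = g.subgraph(max(nx.connected_components(g), key=len))
        return nx.diameter(g)

    # -- distances ----------------------------------------------------
    def distance_matrix(self) -> tuple[list[str], dict[str, int], np.ndarray]:
        """All-pairs unweighted hop distances.

        Returns (ordered node labels, label->index map, dense float matrix
        with ``inf`` for unreachable pairs).  Cached on the graph.
        """
        if self._dist_cache is None:
            order = sorted(self._g.nodes)
            adj = nx.to_scipy_sparse_array(self._g, nodelist=order, format="csr")
            dmat = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
            self._dist_cache = (order, {n: i for i, n in enumerate(order)}, dmat)
        return self._dist_cache

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NetworkGraph(name={self.name!r}, n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (disease or pathway membership)."""

    name: str
    genes: frozenset[str]
    category: SetCategory = SetCategory.pathway
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        cleaned = frozenset(g.strip().upper() for g in self.genes if g.strip())
        object.__setattr__(self, "genes", cleaned)

    def __len__(self) -> int:
        return len(self.genes)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_edge_list(path: str | Path, fmt: str = "tsv", name: str | None = None) -> NetworkGraph:
    """Read an undirected graph from a whitespace TSV or Cytoscape SIF file.

    TSV lines hold two whitespace-separated node labels; ``#`` lines are
    comments.  SIF lines hold ``source relation target [target ...]``; a
    one-column SIF line declares an isolated node.  Duplicate and reversed
    edges collapse; self-loops are dropped with a logged count.
    """
    path = Path(path)
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    edges: list[tuple[str, str]] = []
    lone_nodes: list[str] = []
    n_content = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            n_content += 1
            if fmt == "tsv":
                if len(cols) < 2:
                    raise GraphFormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
                edges.append((cols[0], cols[1]))
            else:  # sif
                if len(cols) == 1:
                    lone_nodes.append(cols[0])
                elif len(cols) == 2:
                    raise GraphFormatError(
                        f"{path}:{lineno}: SIF line needs source, relation and >=1 target"
                    )
                else:
                    src = cols[0]
                    edges.extend((src, tgt) for tgt in cols[2:])
    if n_content == 0:
        raise GraphFormatError(f"{path}: no edges found (empty file)")
    return NetworkGraph(edges, nodes=lone_nodes, name=name if name is not None else path.stem)


def write_edge_list(g: NetworkGraph, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write a graph as a two-column TSV; isolated nodes as single-column SIF-ish lines are not emitted."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")


def read_gmt(path: str | Path, category: SetCategory = SetCategory.pathway) -> list[GeneSet]:
    """Read gene sets from a GMT file (name TAB description TAB gene...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets.append(
                GeneSet(
                    name=cols[0].strip(),
                    genes=frozenset(g for g in cols[2:] if g.strip()),
                    category=category,
                    description=cols[1].strip(),
                )
            )
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *sorted(s.genes)]) + "\n")


def shortest_path_lengths(
    g: NetworkGraph, sources: Iterable[str], targets: Iterable[str]
) -> pd.DataFrame:
    """Hop distances for every (source, target) pair.

    Returns a DataFrame indexed by source with targets as columns;
    unreachable pairs hold ``inf``.
    """
    sources, targets = list(sources), list(targets)
    unknown = [n for n in set(sources) | set(targets) if n not in g]
    if unknown:
        raise KeyError(f"node label(s) not in graph: {sorted(unknown)}")
    _, index, dmat = g.distance_matrix()
    si = [index[s] for s in sources]
    ti = [index[t] for t in targets]
    block = dmat[np.ix_(si, ti)]
    return pd.DataFrame(block, index=sources, columns=targets)
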