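"""Combined networks and centrality-based candidate ranking.

The pathway-overlap network has one node per pathway and an edge
wherever two pathways share at least one gene.  The merged protein
network is the node/edge union of the individual pathway topologies.
Candidate receptors are the union of the top-k genes by degree, node
betweenness and edge betweenness (both endpoints for edges),
intersected with the genes that occur as receptors in the
peptide-complex metadata.

Betweenness is exact (Brandes accumulation via networkx), unnormalised,
over unordered pairs with endpoints excluded for nodes and included for
edges — the conventional raw counts; since only ranks are consumed
downstream, any monotone convention is equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .graph_core import GeneSet, NetworkGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityTable",
    "pathway_overlap_network",
    "merge_protein_network",
    "centrality_rankings",
    "select_candidates",
]


@dataclass
class CentralityTable:
    nodes: pd.DataFrame  # index node; columns degree, betweenness, top_degree, top_betweenness
    edges: pd.DataFrame  # index (u, v) sorted tuple; columns betweenness, top_betweenness
    top_k: int

    def top_nodes(self, measure: str) -> list[str]:
        return sorted(self.nodes.index[self.nodes[f"top_{measure}"]])

    def top_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges.index[self.edges["top_betweenness"]])


def pathway_overlap_network(pathways: list[GeneSet], name: str = "pathway_overlap") -> NetworkGraph:
    """Pathway nodes, edge iff the two pathways share at least one gene."""
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways")
    edges = [
        (a.name, b.name)
        for i, a in enumerate(pathways)
        for b in pathways[i + 1 :]
        if a.genes & b.genes
    ]
    return NetworkGraph(edges, nodes=[p.name for p in pathways], name=name)


def merge_protein_network(topologies: list[NetworkGraph], name: str = "merged_protein") -> NetworkGraph:
    """Node and edge union of the pathway topologies (idempotent)."""
    if not topologies:
        raise ValueError("need at least one topology")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for t in topologies:
        nodes |= t.nodes
        edges |= {tuple(sorted(e)) for e in t.edges}
    return NetworkGraph(edges, nodes=nodes, name=name)


def _top_flags(series: pd.Series, k: int) -> pd.Series:
    """Flag the top-k values; ties at the k-th rank are all included."""
    if len(series) <= k:
        return pd.Series(True, index=series.index)
    cutoff = series.sort_values(ascending=False).iloc[k - 1]
    flags = series >= cutoff
    if flags.sum() > k:
        logger.info("tie at rank %d: keeping %d entries", k, int(flags.sum()))
    return flags


def centrality_rankings(g: NetworkGraph, top_k: int = 10) -> CentralityTable:
    """Degree, node betweenness and edge betweenness with top-k flags."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    nxg = g.to_networkx()
    node_btw = nx.betweenness_centrality(nxg, normalized=False)
    edge_btw = nx.edge_betweenness_centrality(nxg, normalized=False)
    nodes = pd.DataFrame(
        {
            "degree": pd.Series({n: nxg.degree(n) for n in nxg.nodes}, dtype=float),
            "betweenness": pd.Series(node_btw),
        }
    ).sort_index()
    nodes["top_degree"] = _top_flags(nodes["degree"], top_k)
    nodes["top_betweenness"] = _top_flags(nodes["betweenness"], top_k)
    edges = pd.DataFrame(
        {"betweenness": pd.Series({tuple(sorted(e)): v for e, v in edge_btw.items()})}
    ).sort_index()
    if len(edges):
        edges["top_betweenness"] = _top_flags(edges["betweenness"], top_k)
    else:
        edges["top_betweenness"] = pd.Series(dtype=bool)
    return CentralityTable(nodes, edges, top_k)


def select_candidates(table: CentralityTable, receptor_genes: set[str]) -> list[str]:
    """Top-central genes that occur as peptide-complex receptors.

    The union of top-k genes over degree, node betweenness, and edge
    betweenness (both endpoints of a top edge) is intersected with the
    receptor genes of the complex metadata.
    """
    top: set[str] = set(table.top_nodes("degree")) | set(table.top_nodes("betweenness"))
    for u, v in table.top_edges():
        top |= {u, v}
    return sorted(top & {r.strip().upper() for r in receptor_genes})
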