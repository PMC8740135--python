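"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations kept separate from the package code:
Floyd-Warshall all-pairs distances, exhaustive nearest-neighbour set
distances, a log-factorial hypergeometric tail, subset-enumeration orbit
counting with its own graphlet reference list, exhaustive-permutation
assignment, and path-enumeration betweenness.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def floyd_warshall(g: nx.Graph) -> dict[tuple, float]:
    nodes = sorted(g.nodes)
    d = {(u, v): (0 if u == v else (1 if g.has_edge(u, v) else math.inf)) for u in nodes for v in nodes}
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def nearest_neighbor_means(g: nx.Graph, a: set, b: set) -> tuple[float, float, float]:
    """(d_aa, d_bb, d_ab) by exhaustive search; nearest-other-member convention."""
    d = floyd_warshall(g)

    def internal(s: set) -> float:
        vals = []
        for x in s:
            best = min((d[x, y] for y in s if y != x), default=math.inf)
            if math.isfinite(best):
                vals.append(best)
        return sum(vals) / len(vals)

    def cross(s: set, t: set) -> float:
        vals = []
        for x in s:
            m = min(d[x, y] for y in t)
            if math.isfinite(m):
                vals.append(m)
        for y in t:
            m = min(d[y, x] for x in s)
            if math.isfinite(m):
                vals.append(m)
        return sum(vals) / len(vals)

    return internal(a), internal(b), cross(a, b)


def hypergeom_upper_tail(k_min: int, ot: int, oh: int, gt: int) -> float:
    """P[X >= k_min] for X ~ Hypergeom(ot, oh, gt), via log-factorials."""

    def lchoose(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -math.inf
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = lchoose(ot, gt)
    total = 0.0
    for k in range(max(k_min, 0), min(oh, gt) + 1):
        num = lchoose(oh, k) + lchoose(ot - oh, gt - k)
        if math.isfinite(num):
            total += math.exp(num - denom)
    return min(total, 1.0)


# -- orbit counting oracle (graphlets on 2-4 nodes) --------------------

_REF_GRAPHLETS = [
    # (size, edges, orbit of each reference node)
    (2, [(0, 1)], [0, 0]),
    (3, [(0, 1), (1, 2)], [1, 2, 1]),
    (3, [(0, 1), (1, 2), (0, 2)], [3, 3, 3]),
    (4, [(0, 1), (1, 2), (2, 3)], [4, 5, 5, 4]),
    (4, [(0, 1), (0, 2), (0, 3)], [7, 6, 6, 6]),
    (4, [(0, 1), (1, 2), (2, 3), (0, 3)], [8, 8, 8, 8]),
    (4, [(0, 1), (1, 2), (1, 3), (2, 3)], [9, 11, 10, 10]),
    (4, [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)], [12, 13, 13, 12]),
    (4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], [14, 14, 14, 14]),
]


def orbit_counts_bruteforce(g: nx.Graph, max_size: int = 4) -> dict:
    """node -> list of 15 orbit counts, by enumerating all node subsets."""
    refs = []
    for size, edges, orbits in _REF_GRAPHLETS:
        if size <= max_size:
            h = nx.Graph(edges)
            refs.append((h, orbits))
    counts = {n: [0] * 15 for n in g.nodes}
    for size in range(2, max_size + 1):
        for subset in itertools.combinations(sorted(g.nodes), size):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for ref, orbits in refs:
                if ref.number_of_nodes() != size:
                    continue
                gm = nx.isomorphism.GraphMatcher(sub, ref)
                if gm.is_isomorphic():
                    for node, refnode in gm.mapping.items():
                        counts[node][orbits[refnode]] += 1
                    break
    return counts


def assignment_bruteforce(c: np.ndarray) -> float:
    """Minimal assignment cost by exhaustive permutation search (vectorised)."""
    n = c.shape[0]
    perms = np.array(list(itertools.permutations(range(n))))
    return float(c[np.arange(n), perms].sum(axis=1).min())


def betweenness_bruteforce(g: nx.Graph) -> tuple[dict, dict]:
    """Node (endpoints excluded) and edge betweenness over unordered pairs."""
    nodes = sorted(g.nodes)
    nb = {n: 0.0 for n in nodes}
    eb = {tuple(sorted(e)): 0.0 for e in g.edges}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            w = 1.0 / len(paths)
            for p in paths:
                for v in p[1:-1]:
                    nb[v] += w
                for u, v in zip(p, p[1:]):
                    eb[tuple(sorted((u, v)))] += w
    return nb, eb
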