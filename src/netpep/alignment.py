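"""Alignment-based network similarity via random-walk entropy signatures.

Each node is described by the Shannon entropies of its row in the t-step
random-walk transition matrix, normalised by ln(N) (the entropy of the
uniform distribution over the graph's nodes), evaluated over a doubling
time schedule t = 1, 2, 4, ... up to the first power of two at or above
twice the larger hop diameter of the pair being compared.  Two nodes a
(in G) and b (in W) are compared by the squared-difference cost

    C_ab = sum_t (M_G[a, t] - M_W[b, t])^2

and the minimal-cost perfect matching of the two node sets (Hungarian
method; the smaller graph is padded with all-zero signature rows acting
as isolated dummy nodes) gives the alignment cost.  The similarity is

    S_AE = exp(-total_cost / n)

with n the padded size, so a zero-cost alignment (e.g. isomorphic
graphs) scores exactly 1 and the score stays in (0, 1].  The integrated
pathway-pair similarity adds the alignment-free component:
S = S_GDD + S_AE, in (0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .graph_core import NetworkGraph
from .graphlets import gdd_agreement

__all__ = [
    "EntropySignature",
    "AlignmentResult",
    "SimilarityResult",
    "transition_matrix",
    "entropy_signature",
    "time_schedule",
    "cost_matrix",
    "align",
    "s_ae",
    "integrated_score",
]

_PLOGP_EPS = 1e-15  # entries below this are treated as exact zeros inside p*ln(p)


@dataclass
class EntropySignature:
    graph_name: str
    nodes: list[str]
    m: np.ndarray  # (n_nodes, n_times), normalised entropies in [0, 1]
    times: list[int]


@dataclass
class AlignmentResult:
    assignment: list[tuple[int, int]]
    total_cost: float
    s_ae: float


@dataclass
class SimilarityResult:
    graph_a: str
    graph_b: str
    s_gdd: float
    s_ae: float
    s_integrated: float


def transition_matrix(g: NetworkGraph) -> tuple[list[str], np.ndarray]:
    """Row-stochastic random-walk matrix; isolated nodes are self-absorbing."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    order = sorted(g.nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    t = np.zeros((n, n))
    for e in g.edges:
        u, v = tuple(e)
        t[index[u], index[v]] = 1.0
        t[index[v], index[u]] = 1.0
    deg = t.sum(axis=1)
    for i in range(n):
        if deg[i] == 0:
            t[i, i] = 1.0
        else:
            t[i] /= deg[i]
    return order, t


def _row_entropies(a: np.ndarray) -> np.ndarray:
    p = np.where(a > _PLOGP_EPS, a, 1.0)  # p*ln(p) -> 0 for (near-)zero entries
    return -(np.where(a > _PLOGP_EPS, a, 0.0) * np.log(p)).sum(axis=1)


def entropy_signature(g: NetworkGraph, times: list[int]) -> EntropySignature:
    """Normalised t-step transition entropies for each node at each scheduled t."""
    if not times or any(t < 1 for t in times):
        raise ValueError("times must be non-empty positive integers")
    order, t1 = transition_matrix(g)
    n = len(order)
    norm = np.log(n) if n > 1 else 1.0  # single-node graph: entropies defined as 0
    m = np.empty((n, len(times)))
    # powers by repeated squaring along the sorted (doubling) schedule
    cache: dict[int, np.ndarray] = {1: t1}

    def power(t: int) -> np.ndarray:
        if t in cache:
            return cache[t]
        if t % 2 == 0:
            half = power(t // 2)
            cache[t] = half @ half
        else:
            cache[t] = power(t - 1) @ t1
        return cache[t]

    for k, t in enumerate(times):
        m[:, k] = _row_entropies(power(t)) / norm
    return EntropySignature(g.name, order, np.clip(m, 0.0, 1.0), list(times))


def time_schedule(g: NetworkGraph, w: NetworkGraph) -> list[int]:
    """Powers of two 1, 2, 4, ... ending at the first power >= 2D.

    D is the larger hop diameter of the pair (computed on each graph's
    largest connected component).
    """
    d = max(g.diameter(), w.diameter())
    target = max(2 * d, 2)
    times = [1]
    while times[-1] < target:
        times.append(times[-1] * 2)
    return times


def cost_matrix(mg: EntropySignature, mw: EntropySignature) -> np.ndarray:
    """Squared-difference signature costs, zero-padded to square."""
    if mg.times != mw.times:
        raise ValueError("entropy signatures computed on different time schedules")
    n = max(len(mg.nodes), len(mw.nodes))
    k = len(mg.times)
    a = np.zeros((n, k))
    b = np.zeros((n, k))
    a[: len(mg.nodes)] = mg.m
    b[: len(mw.nodes)] = mw.m
    diff = a[:, None, :] - b[None, :, :]
    return (diff**2).sum(axis=2)


def align(c: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Minimal-total-cost perfect matching of a square non-negative cost matrix."""
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("cost matrix must be square")
    rows, cols = linear_sum_assignment(c)
    return list(zip(rows.tolist(), cols.tolist())), float(c[rows, cols].sum())


def s_ae(g: NetworkGraph, w: NetworkGraph) -> float:
    """Alignment-based similarity in (0, 1]; 1 iff a zero-cost alignment exists."""
    return align_graphs(g, w).s_ae


def align_graphs(g: NetworkGraph, w: NetworkGraph) -> AlignmentResult:
    times = time_schedule(g, w)
    c = cost_matrix(entropy_signature(g, times), entropy_signature(w, times))
    assignment, cost = align(c)
    return AlignmentResult(assignment, cost, float(np.exp(-cost / c.shape[0])))


def integrated_score(g: NetworkGraph, w: NetworkGraph, max_graphlet_size: int = 4) -> SimilarityResult:
    """S = S_GDD + S_AE; higher means structurally more similar."""
    sg = gdd_agreement(g, w, max_graphlet_size).s_gdd
    sa = s_ae(g, w)
    return SimilarityResult(g.name, w.name, sg, sa, sg + sa)
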