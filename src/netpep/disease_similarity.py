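"""Disease-module separation on an interactome.

Two disease gene sets are compared by where their genes sit on the
protein-protein interaction network.  The separation score

    S_ab = <d_ab> - (<d_aa> + <d_bb>) / 2

contrasts the mean cross-set nearest-neighbour hop distance <d_ab>
against the two within-set means.  Low / negative S means the two
disease neighbourhoods overlap on the interactome, i.e. the diseases are
network-similar.

Significance comes from a degree-preserving permutation null: random
gene sets matched to the observed sets in size and degree profile
(logarithmic degree bins) give a null distribution of S, from which a
z-score is formed; a two-sided Mann-Whitney U test compares the observed
cross-distance sample against the pooled null cross-distance samples,
and Benjamini-Hochberg FDR turns the p-values into q-values across all
disease pairs.

Sign convention: the z reported and filtered on is the *similarity*
z-score  z = (mean(S_null) - S_obs) / sd(S_null), so larger z means more
similar than the null.  This is stated in every output header.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_core import GeneSet, NetworkGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SeparationResult",
    "mean_internal_distance",
    "mean_between_distance",
    "separation_score",
    "permutation_test",
    "fdr_adjust",
    "filter_similar_pairs",
    "disease_pair_table",
]

#: default significance thresholds for the pair filter
Z_MIN_DEFAULT = 1.6
Q_MAX_DEFAULT = 0.001


@dataclass
class SeparationResult:
    disease_i: str
    disease_j: str
    d_ii: float
    d_jj: float
    d_ij: float
    s_ij: float
    z_score: float
    p_value: float
    q_value: float = math.nan

    @property
    def passes(self) -> bool:
        return self.z_score >= Z_MIN_DEFAULT and self.q_value <= Q_MAX_DEFAULT


def _mapped_indices(g: NetworkGraph, s: GeneSet) -> np.ndarray:
    _, index, _ = g.distance_matrix()
    idx = [index[x] for x in s.genes if x in index]
    n_missing = len(s.genes) - len(idx)
    if n_missing:
        logger.info("%d/%d genes of %r absent from interactome", n_missing, len(s.genes), s.name)
    return np.asarray(sorted(idx), dtype=np.intp)


def _internal_mean(dmat: np.ndarray, idx: np.ndarray) -> float:
    """Mean over genes of the hop distance to the nearest *other* gene of the set."""
    sub = dmat[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    finite = nearest[np.isfinite(nearest)]
    if finite.size == 0:
        raise ValueError("disconnected set: no finite internal distance")
    if finite.size < nearest.size / 2:
        logger.warning("more than half of the set has no reachable same-set partner")
    return float(finite.mean())


def _cross_nearest(dmat: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Per-gene nearest other-set distance over a union b (finite values only)."""
    block = dmat[np.ix_(ia, ib)]
    vals = np.concatenate([block.min(axis=1), block.min(axis=0)])
    return vals[np.isfinite(vals)]


def mean_internal_distance(g: NetworkGraph, a: GeneSet) -> float:
    """<d_aa>: mean nearest-same-set hop distance of the mapped genes of *a*."""
    idx = _mapped_indices(g, a)
    if idx.size < 2:
        raise ValueError(f"degenerate disease set {a.name!r}: fewer than 2 genes map")
    _, _, dmat = g.distance_matrix()
    return _internal_mean(dmat, idx)


def mean_between_distance(g: NetworkGraph, a: GeneSet, b: GeneSet) -> float:
    """<d_ab>: mean nearest-other-set hop distance over genes of a union b.

    Genes shared by both sets contribute distance 0, so identical sets give 0.
    """
    ia, ib = _mapped_indices(g, a), _mapped_indices(g, b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("a set has no mapped genes")
    _, _, dmat = g.distance_matrix()
    vals = _cross_nearest(dmat, ia, ib)
    if vals.size == 0:
        raise ValueError(f"disconnected sets: no finite cross distance {a.name!r}/{b.name!r}")
    return float(vals.mean())


def separation_score(g: NetworkGraph, a: GeneSet, b: GeneSet) -> float:
    """S_ab = <d_ab> - (<d_aa> + <d_bb>)/2."""
    return mean_between_distance(g, a, b) - (
        mean_internal_distance(g, a) + mean_internal_distance(g, b)
    ) / 2.0


# ----------------------------------------------------------------------
# degree-binned permutation null
# ----------------------------------------------------------------------

def _degree_bins(g: NetworkGraph, min_bin: int = 20) -> dict[int, np.ndarray]:
    """Bin node indices by degree into logarithmic bins of >=min_bin nodes.

    Returns degree -> array of candidate node indices sharing that
    degree's (merged) bin.  Small bins are merged upward.
    """
    order, _, _ = g.distance_matrix()
    degs = np.array([g.degree(n) for n in order])
    uniq = np.unique(degs)
    # logarithmic bin edges over the degree range
    lo, hi = max(int(uniq.min()), 0), int(uniq.max())
    edges = [lo]
    d = max(lo, 1)
    while d <= hi:
        d = max(int(math.ceil(d * 2)), d + 1)
        edges.append(d)
    bins: list[list[int]] = []
    bin_of_degree: dict[int, int] = {}
    for k in range(len(edges)):
        top = edges[k + 1] if k + 1 < len(edges) else hi + 1
        members = np.nonzero((degs >= edges[k]) & (degs < top))[0]
        bins.append(list(members))
        for dd in range(edges[k], top):
            bin_of_degree[dd] = k
    # merge small bins upward (toward higher-degree neighbour)
    for k in range(len(bins) - 1):
        if 0 < len(bins[k]) < min_bin:
            bins[k + 1].extend(bins[k])
            for dd, b in bin_of_degree.items():
                if b == k:
                    bin_of_degree[dd] = k + 1
            bins[k] = []
    # a trailing small bin merges downward into the nearest non-empty one
    if 0 < len(bins[-1]) < min_bin:
        for k in range(len(bins) - 2, -1, -1):
            if bins[k]:
                bins[k].extend(bins[-1])
                for dd, b in bin_of_degree.items():
                    if b == len(bins) - 1:
                        bin_of_degree[dd] = k
                bins[-1] = []
                break
    return {dd: np.asarray(bins[b], dtype=np.intp) for dd, b in bin_of_degree.items() if bins[b].__len__()}


def _sample_matched(
    rng: np.random.Generator, g: NetworkGraph, idx: np.ndarray, bins: dict[int, np.ndarray]
) -> np.ndarray:
    """Random node-index set matching idx's degree-bin profile, without replacement."""
    order, _, _ = g.distance_matrix()
    chosen: list[int] = []
    taken: set[int] = set()
    for i in idx:
        pool = bins[g.degree(order[i])]
        pick = int(pool[rng.integers(pool.size)])
        for _ in range(50):
            if pick not in taken:
                break
            pick = int(pool[rng.integers(pool.size)])
        taken.add(pick)
        chosen.append(pick)
    return np.asarray(sorted(set(chosen)), dtype=np.intp)


def permutation_test(
    g: NetworkGraph,
    a: GeneSet,
    b: GeneSet,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Similarity z-score and Mann-Whitney p-value for the pair (a, b).

    The null draws ``n_perm`` random gene-set pairs matched to a and b in
    size and degree-bin profile and recomputes S.  Returns

    * the raw z = (S_obs - mean(S_null)) / sd(S_null); a strongly
      *negative* raw z means the pair is more similar than the null
      (:func:`disease_pair_table` reports the negated, similarity-signed
      z that the pair filter thresholds), and
    * the two-sided Mann-Whitney U p-value of the observed cross-distance
      sample against the pooled null cross-distance samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ia, ib = _mapped_indices(g, a), _mapped_indices(g, b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("degenerate disease set: fewer than 2 genes map")
    _, _, dmat = g.distance_matrix()

    def score(i1: np.ndarray, i2: np.ndarray) -> tuple[float, np.ndarray]:
        cross = _cross_nearest(dmat, i1, i2)
        s = cross.mean() - (_internal_mean(dmat, i1) + _internal_mean(dmat, i2)) / 2.0
        return float(s), cross

    s_obs, cross_obs = score(ia, ib)
    bins = _degree_bins(g)
    null_s = np.empty(n_perm)
    null_cross: list[np.ndarray] = []
    for k in range(n_perm):
        ra = _sample_matched(rng, g, ia, bins)
        rb = _sample_matched(rng, g, ib, bins)
        while ra.size < 2:
            ra = _sample_matched(rng, g, ia, bins)
        while rb.size < 2:
            rb = _sample_matched(rng, g, ib, bins)
        null_s[k], nc = score(ra, rb)
        null_cross.append(nc)
    sd = float(null_s.std(ddof=1))
    if sd == 0.0:
        logger.warning("null separation has zero spread; z reported as +/-inf")
        z = math.inf if s_obs > null_s.mean() else (-math.inf if s_obs < null_s.mean() else 0.0)
    else:
        z = (s_obs - float(null_s.mean())) / sd
    pooled = np.concatenate(null_cross)
    if np.all(pooled == pooled[0]) and np.all(cross_obs == pooled[0]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(cross_obs, pooled, alternative="two-sided").pvalue)
    return z, p


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to [0, 1]."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def disease_pair_table(
    g: NetworkGraph,
    diseases: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[SeparationResult]:
    """Separation statistics for every unordered disease pair, with q-values."""
    rng = np.random.default_rng(seed)
    results: list[SeparationResult] = []
    for i in range(len(diseases)):
        for j in range(i + 1, len(diseases)):
            a, b = diseases[i], diseases[j]
            d_ii = mean_internal_distance(g, a)
            d_jj = mean_internal_distance(g, b)
            d_ij = mean_between_distance(g, a, b)
            s = d_ij - (d_ii + d_jj) / 2.0
            z_raw, p = permutation_test(g, a, b, n_perm=n_perm, seed=rng)
            # similarity sign convention: larger z = more similar than null
            results.append(SeparationResult(a.name, b.name, d_ii, d_jj, d_ij, s, -z_raw, p))
    q = fdr_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def filter_similar_pairs(
    results: list[SeparationResult],
    z_min: float = Z_MIN_DEFAULT,
    q_max: float = Q_MAX_DEFAULT,
) -> list[SeparationResult]:
    """Pairs with similarity z >= z_min and q <= q_max (inclusive bounds)."""
    return [r for r in results if r.z_score >= z_min and r.q_value <= q_max]
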