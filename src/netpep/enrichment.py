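"""EASE-score enrichment of disease gene sets against pathway gene sets.

The EASE score is a conservative variant of the one-tailed Fisher exact
test: one observed hit is removed before taking the hypergeometric upper
tail, which penalises pathways supported by a single gene.  With
GH = disease genes in the pathway, GT = disease genes in the universe,
OH = universe genes in the pathway and OT = universe size,

    e = P[X >= GH - 1],   X ~ Hypergeom(OT, OH, GT)

and e = 1 whenever GH <= 1.  A pathway counts as enriched when its best
(smallest) e over the diseases is at or below the threshold (default
0.05, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .graph_core import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "ease_score",
    "enrich",
    "intersect_common_pathways",
]

E_THRESHOLD_DEFAULT = 0.05


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 enrichment counts: gene hits / gene total / genome hits / genome total."""

    gh: int
    gt: int
    oh: int
    ot: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.gh <= min(self.gt, self.oh)
            and self.gt <= self.ot
            and self.oh <= self.ot
            # hits cannot exceed what the complement allows
            and self.gt - self.gh <= self.ot - self.oh
        )
        if not ok:
            raise ValueError(f"impossible contingency counts {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    disease: str
    pathway: str
    counts: ContingencyCounts
    e_value: float


def ease_score(c: ContingencyCounts) -> float:
    """One-tailed hypergeometric upper tail with one hit removed."""
    if c.gh <= 1:
        return 1.0
    # P[X >= gh-1] = sf(gh-2)
    return float(min(1.0, hypergeom.sf(c.gh - 2, c.ot, c.oh, c.gt)))


def enrich(
    diseases: list[GeneSet],
    pathways: list[GeneSet],
    universe: set[str] | None = None,
    threshold: float = E_THRESHOLD_DEFAULT,
) -> tuple[list[EnrichmentResult], list[str]]:
    """EASE enrichment of every (disease, pathway) pair.

    Genes outside the universe are dropped with a logged count.  Returns
    the per-pair results and the names of pathways whose minimum e over
    diseases is <= threshold (inclusive), sorted.
    """
    if universe is None:
        universe = set().union(*(p.genes for p in pathways)) if pathways else set()
    if not universe:
        raise ValueError("empty gene universe")
    ot = len(universe)
    results: list[EnrichmentResult] = []
    best: dict[str, float] = {}
    for d in diseases:
        dg = d.genes & universe
        dropped = len(d.genes) - len(dg)
        if dropped:
            logger.info("%d genes of %r outside universe dropped", dropped, d.name)
        for p in pathways:
            pg = p.genes & universe
            c = ContingencyCounts(gh=len(dg & pg), gt=len(dg), oh=len(pg), ot=ot)
            e = ease_score(c)
            results.append(EnrichmentResult(d.name, p.name, c, e))
            best[p.name] = min(best.get(p.name, 1.0), e)
    enriched = sorted(n for n, e in best.items() if e <= threshold)
    return results, enriched


def intersect_common_pathways(
    enriched: list[str],
    drug_pathways: list[str],
    aliases: dict[str, str] | None = None,
) -> list[str]:
    """Sorted intersection of enriched and drug-related pathway names.

    ``aliases`` optionally maps raw names to canonical identifiers before
    intersecting (for pathways present under different database names).
    """
    def canon(name: str) -> str:
        n = name.strip()
        return (aliases or {}).get(n, n)

    left = {canon(n) for n in enriched}
    right = {canon(n) for n in drug_pathways}
    return sorted(left & right)
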