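# Methods

## Disease module separation

Two disease gene sets `a`, `b` are compared on an undirected, unweighted
interactome. For each gene we take the hop distance to the nearest *other*
gene of the relevant set; `<d_aa>` averages nearest-same-set distances over
the genes of `a`, and `<d_ab>` averages nearest-other-set distances over the
genes of `a ∪ b`. The separation score is
`S_ab = <d_ab> − (<d_aa> + <d_bb>)/2`. The nearest-neighbour (not all-pairs)
convention is the one used in the disease-module literature this statistic
comes from; it makes `S_aa = −<d_aa>` for a set compared with itself and `S = 0`
for interleaved sets on a clique. Genes absent from the interactome are
dropped with a logged count; infinite distances are excluded from means, with
a warning when more than half a set is unreachable.

**Null model.** Interactome nodes are binned by degree into logarithmic bins
(bins smaller than 20 nodes merged with their higher-degree neighbour), and
each null draw samples, per observed gene, a random node from that gene's
degree bin, avoiding repeats. This matches null sets to the observed sets in
size and degree profile — necessary because hubs are systematically closer to
everything. From `n_perm` draws we form `z = (S_obs − mean S_null)/sd S_null`;
a strongly negative raw z means the pair is closer than degree-matched chance.
Reported tables and the pair filter use the negated, similarity-signed z
(larger = more similar), stated in every output header. The p-value is a
two-sided Mann–Whitney U comparing the observed per-gene cross distances with
the pooled null cross distances (the test's two samples are otherwise
unspecified in this family of methods; pooling the null draws gives a stable
reference sample). Benjamini–Hochberg FDR across all pairs yields q-values.
Defaults: `n_perm = 1000`, filter `z ≥ 1.6`, `q ≤ 0.001`, both inclusive.

## EASE enrichment

With GH = disease genes in the pathway, GT = disease genes in the universe,
OH = universe genes in the pathway, OT = universe size, the EASE score is the
one-tailed hypergeometric upper tail with one hit removed:
`e = P[X ≥ GH−1]`, `X ~ Hypergeom(OT, OH, GT)`, and `e = 1` whenever
`GH ≤ 1`. This is the standard "modified Fisher exact" definition; it is
implemented via `scipy.stats.hypergeom.sf` and cross-checked in the tests
against a log-factorial tail summation. The universe defaults to the union of
all pathway gene sets (overridable), genes outside it are dropped with a
warning, and a pathway is *enriched* when its minimum e over diseases is at or
below the threshold (default 0.05, inclusive). No multiple-testing correction
is applied at this stage by default. Pathway names can be canonicalised
through an alias table before intersecting with the drug-pathway list.

## Graphlet degree distribution agreement (S_GDD)

Orbits of the connected graphlets on 2–4 nodes (15 orbits, default) or 2–5
nodes (73 orbits, by flag) are counted exactly per node: connected induced
subgraphs are enumerated with Wernicke's ESU algorithm and classified via a
precomputed table from the subgraph's adjacency bitmask to the orbit of each
position. Orbits 0–14 follow the standard published numbering (orbit 0 =
degree, 1/2 = path-of-3 end/middle, 3 = triangle, …, 14 = 4-clique). For the
21 five-node graphlets the 58 orbits are ordered by a deterministic canonical
sort (edge count, degree sequence, canonical code; orbits within a graphlet by
degree, orbit size, canonical position). This ordering is fixed and identical
for every graph, which is all GDD comparison requires; it is not guaranteed to
coincide with the published size-5 numbering.

For orbit j, `d^j(k)` counts nodes touching the orbit exactly k times; bins
are scaled by 1/k (k = 0 is excluded — nodes never touching an orbit
contribute nothing) and normalised to unit sum, and the per-orbit agreement is
`1 − ||N_G − N_W||_2 / √2`. The 1/√2 factor maps the maximal distance between
two unit-sum non-negative vectors (disjoint supports) to agreement 0, keeping
every agreement in [0, 1]. Two empty orbits agree perfectly (1); an occupied
versus unoccupied orbit scores 0, treating presence/absence of a structural
feature as maximal disagreement. `S_GDD` is the arithmetic mean over orbits.
The default `max_graphlet_size = 4` keeps exact enumeration fast at pathway
scale; exact size-5 counting is refused above 5000 nodes.

## Entropy-signature alignment (S_AE)

The random-walk transition matrix divides each adjacency row by its degree
(isolated nodes are self-absorbing). For each time t in the schedule —
powers of two 1, 2, 4, … up to the first power ≥ 2D, with D the larger hop
diameter of the pair (largest component, with a warning if disconnected) —
the t-step matrix is computed by repeated squaring, and each node's row
entropy `−Σ p ln p` (entries below 1e-15 treated as zero) is normalised by
`ln N`, the entropy of the uniform distribution over the graph's nodes. The
schedule includes t = 1 so that purely local structure participates.

The cost between node a of G and node b of W is
`C_ab = Σ_t (M_G[a,t] − M_W[b,t])²`; when sizes differ, the smaller signature
is padded with all-zero rows (virtual isolated nodes, the natural meaning of
"use the larger node count"). The Hungarian method
(`scipy.optimize.linear_sum_assignment`) gives the minimal-cost perfect
matching, and the similarity is `S_AE = exp(−total_cost / n)` with n the
padded size. The exponential-of-mean-cost mapping is this package's design
choice: the cost-to-similarity mapping is otherwise undefined for this
statistic, and this one is bounded in (0, 1], equals 1 exactly for zero-cost
(e.g. isomorphic) pairs, and decreases monotonically in cost. Absolute `S_AE`
values are therefore comparable only within a run; ordering, not scale,
is the meaningful output. The integrated score is `S = S_GDD + S_AE`.

## Combined networks and ranking

The pathway-overlap network joins two pathways iff their gene sets intersect;
the merged protein network is the set union of the topology node and edge
sets. Betweenness is exact and unnormalised: unordered pairs, endpoints
excluded for nodes, included for edges (networkx's Brandes implementation,
`normalized=False`); on disconnected networks it accrues per component.
Only ranks are consumed, so any monotone convention would give the same
selection. "Top k" (default 10) keeps all entries tied at the k-th value
rather than truncating arbitrarily. Candidates are the union of top genes over
the three measures (both endpoints for edges) intersected with the receptors
of peptides that fall in clusters of at least two members.

## Peptide properties

* **Molecular weight**: sum of average residue masses plus one water
  (18.02 Da); undefined (reported "−") when the sequence contains a
  non-standard letter. Monoisotopic masses by flag.
* **Aromaticity**: (#F + #W + #Y) / length, with X kept in the denominator.
* **Instability index**: Guruprasad's dipeptide-weight statistic,
  `(10/L) Σ DIWV(s_i, s_{i+1})`; > 40 conventionally predicts instability;
  undefined when any dipeptide contains X.
* **Isoelectric point**: bisection on the net charge of the Bjellqvist model
  (residue-specific terminal pKa, side chains D, E, C, Y, H, K, R) to
  |charge| < 1e-4 within pH 0–14; X is uncharged.

Residue masses, DIWV weights and pKa values come from Biopython's ProtParam
data tables; the property logic (undefined-value handling, denominators,
bisection) is implemented here.

## Peptide clustering and consensus

Full profile-HMM clustering is deliberately replaced by a deterministic greedy
profile method adequate for desk-scale panels of short, fixed-register
peptides: peptides are processed longest-first (ties lexicographic); each
joins the existing cluster whose consensus it matches best at gapless
best-offset identity ≥ `min_identity` (default 0.7; identity = matches /
shorter length, X matches nothing) or seeds a new cluster, and a single
refinement pass re-assigns all peptides against the final consensi, making
the result invariant to input order. The consensus aligns members at their
best offsets to the longest member, keeps positions covered by ≥ 50% of
members, and takes the per-position majority residue (ties resolved to the
alphabetically smallest, logged); the full position × residue frequency
matrix is exported. Gapless alignment is lossless for near-identical
fixed-register peptides such as kinase-substrate panels, but will split
families whose similarity requires indels — a known limitation.

## Synthetic bundle

The fixture generator emits the study conditions the pipeline is validated
under: a 300-node preferential-attachment interactome (m = 3, the classic
scale-free regime of curated interactomes at toy scale); six 15-gene disease
sets of which two pairs are planted as similar (8 shared genes drawn from a
hub's two-hop neighbourhood, the rest from the same neighbourhood) and the
remainder uniform random; ten 20-gene pathway sets of which three overlap a
planted disease set by 8 genes, include a designated hub gene, and appear on
the drug-pathway list; per-pathway connected topologies (random spanning tree
plus extra edges) with the hub wired as a within-pathway star in the planted
pathways; and a peptide table containing the reference peptide panel verbatim
plus two generated decoy families (5 peptides each, one point mutation apart),
one carrying the hub as receptor. Generation is deterministic given the seed
and a ground-truth manifest is written alongside.

The generator reproduces degree heterogeneity, module locality and planted
signal, but not literature-scale annotation noise, incomplete gene-to-network
mapping, or weighted/directed interaction semantics — passing tests
demonstrate correctness and calibration of the statistics under these
idealised conditions, not performance on real disease corpora.

## Numerical and testing choices

Distances use scipy's sparse-graph BFS with an explicit `inf` marker for
unreachable pairs, cached per graph. The calibration suite uses 200 random
set pairs at `n_perm = 500` on the 300-node bundle for the null (|z| < 3 in
≥ 99% of instances; q ≤ 0.05 rate ≤ 10%) and 20 generator seeds for
planted-pair recovery — sizes chosen to give stable rates at desk scale.
Brute-force oracles (Floyd–Warshall, subset-enumeration orbit counting,
exhaustive-permutation assignment, shortest-path enumeration betweenness,
log-factorial hypergeometric tails) live in the test suite, independent of
the implementation paths they check.
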