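"""Synthetic study-condition generator.

Emits a complete, self-contained input bundle for the pipeline — an
interactome, disease and pathway gene sets, pathway topologies, a
drug-related pathway list, and a peptide-complex table — together with
a ground-truth manifest of everything that was planted, so that tests
can score recovery.

What it emulates:

* a scale-free interactome (preferential attachment), the degree
  structure that makes a degree-matched permutation null meaningful;
* disease modules as locally dense neighbourhoods; *similar* disease
  pairs share part of a seed region, giving near-zero cross-set
  distances against a null of degree-matched random sets;
* pathway gene sets, a known subset of which heavily overlaps a disease
  module (hence EASE-enriched) and sits on the drug-pathway list — these
  are the planted "common" pathways;
* per-pathway interaction topologies, with one designated hub gene wired
  into every planted pathway so it tops the merged-network centrality
  rankings;
* a peptide-complex table holding the reference peptide panel verbatim
  plus generated decoy families, one family carrying the planted hub as
  its receptor.

It does not emulate literature-scale gene-set noise, annotation bias,
or weighted/directed interaction semantics.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_core import GeneSet, NetworkGraph, SetCategory, write_edge_list, write_gmt
from .peptide_data import REFERENCE_PEPTIDES

__all__ = ["FixtureSpec", "generate_fixtures"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Parameters of the synthetic bundle (defaults are the study conditions)."""

    seed: int = 0
    n_nodes: int = 300
    attachment_m: int = 3
    n_diseases: int = 6
    disease_size: int = 15
    n_shared: int = 8               # genes shared within a planted similar pair
    n_pathways: int = 10
    pathway_size: int = 20
    n_common: int = 3               # planted enriched-and-drug-related pathways
    n_planted_overlap: int = 8      # pathway genes drawn from the target disease
    n_drug_extra: int = 2           # drug-list pathways that are not enriched
    n_decoy_families: int = 2
    decoy_family_size: int = 5
    peptide_length: int = 12


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=min(n_mut, len(s)), replace=False):
        s[pos] = _AA[rng.integers(len(_AA))]
    return "".join(s)


def generate_fixtures(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the bundle under ``out_dir``; return the ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # ---- interactome -------------------------------------------------
    ba = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment_m, seed=int(rng.integers(2**31)))
    names = _gene_names(spec.n_nodes)
    g = NetworkGraph.from_networkx(nx.relabel_nodes(ba, dict(enumerate(names))), name="interactome")
    write_edge_list(g, out / "interactome.tsv", header=[f"fixture interactome seed={spec.seed}"])

    # ---- disease modules --------------------------------------------
    deg = dict(ba.degree())
    hubs = sorted(deg, key=lambda v: -deg[v])
    diseases: list[GeneSet] = []
    planted_pairs: list[tuple[str, str]] = []

    def neighbourhood(center: int) -> list[str]:
        ball = {center} | set(ba.neighbors(center))
        for u in list(ball):
            ball |= set(ba.neighbors(u))
        return sorted(names[v] for v in ball)

    # two planted similar pairs seeded on distinct hub neighbourhoods
    for pair_idx in range(2):
        center = hubs[pair_idx]
        pool = neighbourhood(center)
        shared = list(rng.choice(pool, size=min(spec.n_shared, len(pool)), replace=False))
        pair_names = []
        for k in range(2):
            extra_pool = [x for x in pool if x not in shared]
            n_extra = spec.disease_size - len(shared)
            extra = list(rng.choice(extra_pool, size=min(n_extra, len(extra_pool)), replace=False))
            dname = f"DIS{2 * pair_idx + k:02d}"
            diseases.append(
                GeneSet(dname, frozenset(shared + extra), SetCategory.disease, "planted module")
            )
            pair_names.append(dname)
        planted_pairs.append(tuple(pair_names))
    # remaining diseases: uniform random gene sets (null-like)
    for k in range(4, spec.n_diseases):
        genes = rng.choice(names, size=spec.disease_size, replace=False)
        diseases.append(GeneSet(f"DIS{k:02d}", frozenset(genes), SetCategory.disease, "random"))
    write_gmt(diseases, out / "diseases.gmt")

    # ---- pathways, drug list, topologies ----------------------------
    target_disease = diseases[0]
    hub_gene = names[hubs[0]]
    pathways: list[GeneSet] = []
    planted_common: list[str] = []
    disease_genes = sorted(target_disease.genes)
    for k in range(spec.n_pathways):
        pname = f"PW{k:02d}"
        if k < spec.n_common:
            overlap = list(
                rng.choice(disease_genes, size=min(spec.n_planted_overlap, len(disease_genes)), replace=False)
            )
            rest_pool = [x for x in names if x not in target_disease.genes and x != hub_gene]
            rest = list(rng.choice(rest_pool, size=spec.pathway_size - len(overlap) - 1, replace=False))
            genes = set(overlap + rest + [hub_gene])
            planted_common.append(pname)
        else:
            pool = [x for x in names if x not in target_disease.genes]
            genes = set(rng.choice(pool, size=spec.pathway_size, replace=False))
        pathways.append(GeneSet(pname, frozenset(genes), SetCategory.pathway, "fixture pathway"))
    write_gmt(pathways, out / "pathways.gmt")

    drug_list = planted_common + [f"PW{spec.n_pathways - 1 - i:02d}" for i in range(spec.n_drug_extra)]
    # a drug-list-only name never emitted as a pathway, to exercise name matching
    drug_list = sorted(set(drug_list) | {"DRUG_ONLY_PW"})
    (out / "drug_pathways.txt").write_text("\n".join(drug_list) + "\n")

    topo_dir = out / "topologies"
    topo_dir.mkdir(exist_ok=True)
    overlap_pairs = 0
    for i, a in enumerate(pathways):
        for b in pathways[i + 1 :]:
            if a.genes & b.genes:
                overlap_pairs += 1
    for p in pathways:
        glist = sorted(p.genes)
        n = len(glist)
        # random spanning tree plus extra edges -> connected topology
        perm = list(rng.permutation(n))
        edges = {(glist[perm[i]], glist[perm[rng.integers(i)]]) for i in range(1, n)}
        for _ in range(n // 2):
            u, v = rng.choice(n, size=2, replace=False)
            edges.add((glist[u], glist[v]))
        if p.name in planted_common:
            # wire the hub gene to every other member: a within-pathway star
            edges |= {(hub_gene, x) for x in glist if x != hub_gene}
        t = NetworkGraph(edges, nodes=glist, name=p.name)
        write_edge_list(t, topo_dir / f"{p.name}.tsv")

    # ---- peptide-complex table --------------------------------------
    rows = [list(r) for r in REFERENCE_PEPTIDES]
    base = "".join(_AA[rng.integers(len(_AA))] for _ in range(spec.peptide_length))
    low_gene = names[hubs[-1]] if deg[hubs[-1]] <= spec.attachment_m else names[min(deg, key=lambda v: deg[v])]
    family_receptors = [hub_gene] + [low_gene] * (spec.n_decoy_families - 1)
    for fam in range(spec.n_decoy_families):
        seed_seq = _mutate(rng, base, spec.peptide_length // 2) if fam else base
        for m in range(spec.decoy_family_size):
            seq = _mutate(rng, seed_seq, 1)
            rows.append(
                [f"fx{fam}{m}", string.ascii_uppercase[m], seq,
                 f"decoy family {fam}", family_receptors[fam]]
            )
    with open(out / "peptides.tsv", "w") as fh:
        fh.write("pdb_id\tchain\tsequence\tdescription\treceptor\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")

    manifest = {
        "spec": asdict(spec),
        "planted_similar_pairs": [list(p) for p in planted_pairs],
        "planted_common_pathways": sorted(planted_common),
        "hub_receptor": hub_gene,
        "pathway_overlap_pairs": overlap_pairs,
        "n_reference_peptides": len(REFERENCE_PEPTIDES),
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
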