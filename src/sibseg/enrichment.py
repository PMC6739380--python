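"""Gene-set over-representation analysis and enrichment-map construction.

The ORA statistic is the exact hypergeometric upper tail P(X >= k) for an
overlap of k query genes with a K-gene set, drawing n genes from a declared
universe of N. Multiple testing uses Benjamini-Hochberg step-up. Significant
sets become nodes of an enrichment map whose edges weight gene overlap
(overlap coefficient by default, Jaccard by flag).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int       # overlap
    K: int       # set size within the universe
    n: int       # query size within the universe
    N: int       # universe size
    p_value: float
    q_value: Optional[float] = None


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def run_ora(query_genes, genesets: GeneSetCollection, universe,
            min_size: int = 3, max_size: int = 500) -> list[EnrichmentResult]:
    """One-sided over-representation of `query_genes` in every gene set.

    Query genes outside the universe are dropped with a warning. Sets are
    intersected with the universe first; sets smaller than `min_size` or
    larger than `max_size` after intersection are skipped. BH correction is
    applied across all tested sets. Results are sorted by p-value.
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query &= universe
    if not query:
        warnings.warn("empty query gene list: no enrichment computed", stacklevel=2)
        return []
    N, n = len(universe), len(query)
    results = []
    for s in genesets:
        set_u = set(s.genes) & universe
        K = len(set_u)
        if K < min_size or K > max_size:
            continue
        k = len(query & set_u)
        results.append(EnrichmentResult(s.set_id, k, K, n, N,
                                        hypergeom_upper(k, K, n, N)))
    if results:
        qs = bh_fdr([r.p_value for r in results])
        results = [EnrichmentResult(r.set_id, r.k, r.K, r.n, r.N, r.p_value, q)
                   for r, q in zip(results, qs)]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def overlap_coefficient(a, b) -> float:
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def build_enrichment_map(results: Sequence[EnrichmentResult],
                         genesets: GeneSetCollection,
                         q_cutoff: float = 0.05,
                         similarity_cutoff: float = 0.375,
                         metric: str = "overlap",
                         universe=None) -> nx.Graph:
    """Build the enrichment-map network.

    Nodes are sets with q <= q_cutoff (attributes: q, size); edges join node
    pairs whose gene-overlap similarity reaches `similarity_cutoff` (0.375 is
    the Enrichment-Map convention). Similarity is computed on the
    universe-intersected gene sets when a universe is given.
    """
    sim = {"overlap": overlap_coefficient, "jaccard": jaccard}[metric]
    graph = nx.Graph(q_cutoff=q_cutoff, similarity_cutoff=similarity_cutoff,
                     metric=metric)
    members = {}
    for r in results:
        if r.q_value is None or r.q_value > q_cutoff:
            continue
        genes = set(genesets[r.set_id].genes)
        if universe is not None:
            genes &= set(universe)
        members[r.set_id] = genes
        graph.add_node(r.set_id, q=r.q_value, size=len(genes))
    ids = sorted(members)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            w = sim(members[a], members[b])
            if w >= similarity_cutoff and w > 0:
                graph.add_edge(a, b, similarity=w)
    return graph


def write_results_tsv(path: str, results: Sequence[EnrichmentResult]):
    import pandas as pd

    pd.DataFrame(
        [{"set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
          "p_value": r.p_value, "q_value": r.q_value} for r in results]
    ).to_csv(path, sep="\t", index=False)


def write_sif(path: str, graph: nx.Graph, edge_attr_path: Optional[str] = None):
    """Export the network as SIF plus an optional edge-attribute TSV; the
    header declares the similarity metric and cutoffs used."""
    lines = [
        f"# enrichment map: metric={graph.graph.get('metric')}, "
        f"q_cutoff={graph.graph.get('q_cutoff')}, "
        f"similarity_cutoff={graph.graph.get('similarity_cutoff')}"
    ]
    connected = set()
    for a, b in sorted(graph.edges()):
        lines.append(f"{a}\toverlaps\t{b}")
        connected |= {a, b}
    for node in sorted(set(graph.nodes()) - connected):
        lines.append(node)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if edge_attr_path is not None:
        rows = ["source\ttarget\tsimilarity"]
        for a, b, data in sorted(graph.edges(data=True)):
            rows.append(f"{a}\t{b}\t{data['similarity']:.6g}")
        with open(edge_attr_path, "w") as fh:
            fh.write("\n".join(rows) + "\n")
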