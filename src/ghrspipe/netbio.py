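"""Symptom -> gene -> pathway network analysis.

Core symptoms are mapped to phenotype-ontology terms (flat lookup, no DAG
propagation), terms to annotated genes, and the genes to the subgraph they
induce in a STRING-style scored interaction network.  Hub genes are those
whose degree reaches twice the network's median degree.  Gene-set
enrichment of the hubs uses the hypergeometric upper tail against a
configurable gene universe, with Benjamini-Hochberg q-values reported
alongside the raw p-values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyStats",
    "map_symptoms_to_terms",
    "genes_for_terms",
    "build_interaction_graph",
    "graph_topology",
    "median_degree",
    "select_hub_nodes",
    "enrich_gene_sets",
]

_TERM_PATTERN = re.compile(r"^[A-Za-z]+:?\w+$")


@dataclass(frozen=True)
class TopologyStats:
    node_count: int
    edge_count: int
    average_degree: float
    average_local_clustering: float
    median_degree: float


def map_symptoms_to_terms(
    core_symptoms, symptom_term_map: dict[str, list[str]]
) -> tuple[set[str], list[str]]:
    """Union of phenotype terms over the core symptoms, plus the unmapped ones.

    Several symptoms may share a term (e.g. the three defecation symptoms
    all map to the constipation term); the union de-duplicates.  Symptoms
    with an empty term list are returned as unmapped.  A core symptom
    missing from the map entirely raises (an empty list is the explicit
    "no counterpart" marker; absence is a data error).
    """
    names = list(core_symptoms.names) if hasattr(core_symptoms, "names") else list(core_symptoms)
    terms: set[str] = set()
    unmapped: list[str] = []
    for symptom in names:
        if symptom not in symptom_term_map:
            raise KeyError(f"core symptom {symptom!r} is absent from the symptom-term map")
        mapped = symptom_term_map[symptom]
        if not mapped:
            unmapped.append(symptom)
            continue
        for term in mapped:
            if not _TERM_PATTERN.match(term):
                raise ValueError(f"malformed term id {term!r} for symptom {symptom!r}")
            terms.add(term)
    return terms, unmapped


def genes_for_terms(terms, term_gene_table: dict[str, list[str]]) -> set[str]:
    """Union of gene symbols annotated to any of the terms."""
    genes: set[str] = set()
    for term in terms:
        annotated = term_gene_table.get(term, [])
        if not annotated:
            logger.info("term %s has no gene annotations", term)
        genes.update(annotated)
    return genes


def build_interaction_graph(genes, edges, min_score: float = 0.4) -> nx.Graph:
    """Subgraph induced on the query genes, keeping edges with score >= cutoff.

    ``edges`` is an iterable of (geneA, geneB, combined_score).  Query
    genes without any retained interaction stay in the graph as isolated
    nodes.
    """
    query = set(genes)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(query))
    for a, b, score in edges:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"interaction score out of [0, 1]: {score}")
        if a == b:
            continue
        if a in query and b in query and score >= min_score:
            graph.add_edge(a, b, score=float(score))
    return graph


def median_degree(graph: nx.Graph) -> float:
    """Median node degree, lower-median convention for even node counts."""
    degrees = sorted(d for _, d in graph.degree())
    return float(degrees[(len(degrees) - 1) // 2])


def graph_topology(graph: nx.Graph) -> TopologyStats:
    """Node/edge counts, average degree 2E/N, mean local clustering, median degree."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = graph.number_of_edges()
    return TopologyStats(
        node_count=n,
        edge_count=e,
        average_degree=2.0 * e / n,
        average_local_clustering=float(nx.average_clustering(graph)),
        median_degree=median_degree(graph),
    )


def select_hub_nodes(graph: nx.Graph, multiplier: float = 2.0, strict: bool = False) -> set[str]:
    """Nodes whose degree reaches ``multiplier`` times the median degree.

    The comparison is non-strict (>=) by default; pass ``strict=True`` for
    a strictly-greater rule.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    cutoff = multiplier * median_degree(graph)
    if strict:
        return {node for node, deg in graph.degree() if deg > cutoff}
    return {node for node, deg in graph.degree() if deg >= cutoff}


def enrich_gene_sets(
    query,
    gene_sets: dict[str, tuple[str, list[str]]] | dict[str, list[str]],
    universe,
    alpha: float = 0.05,
    top_n: int = 20,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    For a universe of N genes, a set of K (after intersecting with the
    universe) and a query of n drawn from the universe, the p-value is the
    upper tail P(X >= overlap) of Hypergeometric(N, K, n).  ``ease``
    decrements the overlap by one before taking the tail (the conservative
    DAVID-style variant).  Benjamini-Hochberg q-values are computed over
    all sets; the returned table is sorted by p ascending, filtered at
    p < alpha, and truncated to ``top_n`` rows.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")

    rows = []
    for name in sorted(gene_sets):
        entry = gene_sets[name]
        if isinstance(entry, tuple):
            category, members = entry
        else:
            category, members = "", entry
        members = set(members) & universe
        overlap = len(query & members)
        k_tail = max(0, overlap - 1) if ease else overlap
        # P(X >= k_tail) = sf(k_tail - 1)
        p = float(hypergeom.sf(k_tail - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "name": name,
                "category": category,
                "overlap_count": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(table["p_value"], method="fdr_bh")
    table["q_value"] = qvals
    table = table.sort_values(["p_value", "name"], kind="stable").reset_index(drop=True)
    return table[table["p_value"] < alpha].head(top_n).reset_index(drop=True)
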