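"""Symptom-gene-pathway multilayer network assembly and export.

The network has three node layers (symptom, gene, pathway) and inter-layer
edges only: a symptom links to a hub gene when the gene is annotated to a
phenotype term mapped from that symptom; a gene links to a pathway when it
is a member of an enriched gene set.  Genes must be connected on both
sides to stay in the network; symptoms and pathways must keep at least one
edge.  Assembly is deterministic (lexicographic node/edge ordering) and
idempotent.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "assemble_tripartite",
    "validate_multilayer",
    "export_network",
    "read_graphml_network",
    "layer_counts",
]

LAYERS = ("symptom", "gene", "pathway")
EDGE_SYMPTOM_GENE = "maps_to"
EDGE_GENE_PATHWAY = "member_of"


def assemble_tripartite(
    symptom_term_map: dict[str, list[str]],
    hub_genes,
    term_gene_table: dict[str, list[str]],
    pathway_sets: dict[str, tuple[str, list[str]]] | dict[str, list[str]],
    enriched_names,
) -> nx.Graph:
    """Build the tripartite network from the upstream stage outputs.

    ``enriched_names`` restricts ``pathway_sets`` to the significant sets
    (e.g. the ``name`` column of the enrichment table).  An empty hub set
    yields an empty network with a warning rather than an error.
    """
    hub_genes = set(hub_genes)
    if not hub_genes:
        logger.warning("empty hub gene set: assembling an empty network")
    enriched = [n for n in sorted(set(enriched_names)) if n in pathway_sets]

    term_genes = {t: set(g) for t, g in term_gene_table.items()}
    sg_edges: set[tuple[str, str]] = set()
    for symptom in sorted(symptom_term_map):
        genes_of_symptom: set[str] = set()
        for term in symptom_term_map[symptom]:
            genes_of_symptom |= term_genes.get(term, set())
        for gene in genes_of_symptom & hub_genes:
            sg_edges.add((symptom, gene))

    gp_edges: set[tuple[str, str]] = set()
    for name in enriched:
        entry = pathway_sets[name]
        members = set(entry[1] if isinstance(entry, tuple) else entry)
        for gene in members & hub_genes:
            gp_edges.add((gene, name))

    # prune genes lacking either side, then edgeless symptoms/pathways
    genes_with_symptom = {g for _, g in sg_edges}
    genes_with_pathway = {g for g, _ in gp_edges}
    kept_genes = genes_with_symptom & genes_with_pathway
    sg_edges = {(s, g) for s, g in sg_edges if g in kept_genes}
    gp_edges = {(g, p) for g, p in gp_edges if g in kept_genes}

    graph = nx.Graph()
    for s in sorted({s for s, _ in sg_edges}):
        graph.add_node(s, layer="symptom", label=s)
    for g in sorted(kept_genes):
        graph.add_node(g, layer="gene", label=g)
    for p in sorted({p for _, p in gp_edges}):
        graph.add_node(p, layer="pathway", label=p)
    for s, g in sorted(sg_edges):
        graph.add_edge(s, g, interaction=EDGE_SYMPTOM_GENE)
    for g, p in sorted(gp_edges):
        graph.add_edge(g, p, interaction=EDGE_GENE_PATHWAY)
    return graph


def layer_counts(net: nx.Graph) -> dict[str, int]:
    counts = {layer: 0 for layer in LAYERS}
    for _, layer in net.nodes(data="layer"):
        counts[layer] += 1
    return counts


def validate_multilayer(net: nx.Graph) -> None:
    """Raise if the layer-partition invariants are violated."""
    for node, data in net.nodes(data=True):
        if data.get("layer") not in LAYERS:
            raise ValueError(f"node {node!r} has no valid layer tag")
    for a, b in net.edges():
        la, lb = net.nodes[a]["layer"], net.nodes[b]["layer"]
        pair = frozenset((la, lb))
        if pair not in ({"symptom", "gene"}, {"gene", "pathway"}):
            raise ValueError(f"forbidden edge between layers {la} and {lb}: {a!r}-{b!r}")
    for node, data in net.nodes(data=True):
        layers = {net.nodes[nb]["layer"] for nb in net.neighbors(node)}
        if data["layer"] == "gene":
            if layers != {"symptom", "pathway"}:
                raise ValueError(f"gene {node!r} is not connected on both sides")
        elif not layers:
            raise ValueError(f"{data['layer']} node {node!r} has no edges")


def export_network(net: nx.Graph, directory, formats=("graphml", "sif", "csv")) -> dict[str, Path]:
    """Write the network as GraphML, SIF, and/or a node-attribute CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "graphml":
            path = directory / "multilayer.graphml"
            nx.write_graphml(net, path)
        elif fmt == "sif":
            path = directory / "multilayer.sif"
            with open(path, "w") as fh:
                for a, b, kind in sorted(net.edges(data="interaction")):
                    if net.nodes[a]["layer"] != "symptom" and net.nodes[a]["layer"] != "gene":
                        a, b = b, a
                    fh.write(f"{a}\t{kind}\t{b}\n")
        elif fmt == "csv":
            path = directory / "multilayer_nodes.csv"
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["node", "layer", "label"])
                for node in sorted(net.nodes):
                    writer.writerow([node, net.nodes[node]["layer"], net.nodes[node]["label"]])
        else:
            raise ValueError(f"unsupported export format {fmt!r}")
        written[fmt] = path
    return written


def read_graphml_network(path) -> nx.Graph:
    """Read back a GraphML export."""
    return nx.read_graphml(path)
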