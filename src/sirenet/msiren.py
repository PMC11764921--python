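"""Construction of an mRNA signaling-regulatory network from a protein network.

A curated signal-transduction network has protein, complex, and family nodes
(e.g. "PI3K", "TSC1/2").  To analyze it against transcriptomic data, each node
must be rewritten as the gene(s) encoding its precursor mRNA and the edges
re-established from RNA-level interaction databases.  The pipeline has three
steps, each an offline table join (the databases — HGNC/UniProt for
composition, SIGNOR/SignaLink for pathway annotation, OmniPath/NPInter for
interactions — are supplied as TSV snapshots, never queried live):

1. :func:`expand_protein_nodes` — replace every protein/complex node with its
   mapped gene symbol(s); complexes with no mapped member are dropped with
   their edges (the TSC1/2 treatment), complexes with several mapped members
   fan out into one gene node per member (the PI3K -> PIK3CA/PIK3CG
   treatment), each inheriting all incident edges with their signs.
2. :func:`filter_by_pathway_annotation` — keep genes annotated to selected
   signaling pathways, plus an explicit whitelist (the designated initial and
   final nodes).
3. :func:`infer_rna_edges` — keep interaction-table edges between surviving
   genes and prune nodes not lying on any directed path from an initial node
   to a final node.

Default initial nodes are the upstream stimuli BDNF, IGF1, the RAS family
(HRAS/NRAS/KRAS), the PI3K subunits (PIK3CA/PIK3CG) and CAMK2A; the default
final node is EIF4E, the cap-binding endpoint of translation control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network_model import Edge, SignedNetwork

__all__ = [
    "ProteinNode",
    "UnmappedNodeError",
    "DEFAULT_INITIAL_NODES",
    "DEFAULT_FINAL_NODES",
    "expand_protein_nodes",
    "filter_by_pathway_annotation",
    "infer_rna_edges",
    "build_msiren",
]

DEFAULT_INITIAL_NODES = frozenset(
    {"BDNF", "IGF1", "HRAS", "NRAS", "KRAS", "PIK3CA", "PIK3CG", "CAMK2A"}
)
DEFAULT_FINAL_NODES = frozenset({"EIF4E"})


class UnmappedNodeError(KeyError):
    """A plain protein node has no gene mapping and is not marked droppable."""


@dataclass(frozen=True)
class ProteinNode:
    """A node of the protein-level network.

    ``kind`` is ``protein`` (exactly one gene member), ``complex`` or
    ``family`` (one or more members; zero *mapped* members means the node is
    dropped during expansion).
    """

    label: str
    kind: str = "protein"
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "complex", "family"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "protein" and len(self.members) > 1:
            raise ValueError(f"protein node {self.label!r} must have a single member")


def _mapped_genes(label: str, mapping: pd.DataFrame) -> list[str]:
    rows = mapping.loc[mapping["label"] == label, "gene"]
    return sorted(rows.dropna().unique())


def expand_protein_nodes(
    signal_net: SignedNetwork,
    nodes: list[ProteinNode],
    mapping: pd.DataFrame,
    droppable: frozenset[str] | set[str] = frozenset(),
) -> SignedNetwork:
    """Rewrite protein/complex nodes as their mapped gene symbols.

    Parameters
    ----------
    signal_net
        Network over protein-node labels.
    nodes
        Declared node list; every network node label must appear here.
    mapping
        Table with columns ``label``, ``gene``, ``source_db``.
    droppable
        Labels that may silently be removed when unmapped even if of kind
        ``protein`` (per-node override of the complex-dropping default).

    A complex/family node with *k* mapped genes produces *k* gene nodes, each
    inheriting every incident edge with its original sign; with zero mapped
    genes the node and its edges are removed.  An unmapped plain protein node
    raises :class:`UnmappedNodeError` listing all offenders.
    """
    by_label = {n.label: n for n in nodes}
    missing = sorted(signal_net.nodes - by_label.keys())
    if missing:
        raise KeyError(f"network nodes absent from the node list: {missing}")

    expansion: dict[str, list[str]] = {}
    offenders: list[str] = []
    for label in sorted(signal_net.nodes):
        node = by_label[label]
        genes = _mapped_genes(label, mapping)
        if not genes:
            if node.kind in ("complex", "family") or label in droppable:
                expansion[label] = []  # drop with incident edges
            else:
                offenders.append(label)
        else:
            expansion[label] = genes
    if offenders:
        raise UnmappedNodeError(f"unmapped protein nodes: {offenders}")

    edges: list[Edge] = []
    seen: set[Edge] = set()
    for src, tgt, sign in signal_net.edges:
        for gs in expansion[src]:
            for gt in expansion[tgt]:
                e = (gs, gt, sign)
                if e not in seen:
                    seen.add(e)
                    edges.append(e)
    gene_nodes = {g for genes in expansion.values() for g in genes}
    return SignedNetwork(nodes=frozenset(gene_nodes), edges=tuple(edges))


def filter_by_pathway_annotation(
    net: SignedNetwork,
    annot: pd.DataFrame,
    selected_pathways: set[str] | frozenset[str],
    whitelist: set[str] | frozenset[str] = frozenset(),
) -> SignedNetwork:
    """Keep nodes annotated to at least one selected pathway or whitelisted.

    ``annot`` has columns ``gene`` and ``pathway``.  Edges survive when both
    endpoints do.  An empty result is legal.
    """
    if not selected_pathways:
        raise ValueError("selected_pathways must be non-empty")
    annotated = set(annot.loc[annot["pathway"].isin(selected_pathways), "gene"])
    keep = (net.nodes & annotated) | (net.nodes & frozenset(whitelist))
    return net.subnetwork(keep)


def infer_rna_edges(
    gene_nodes: set[str] | frozenset[str],
    interactions: pd.DataFrame,
    initial_nodes: set[str] | frozenset[str],
    final_nodes: set[str] | frozenset[str],
) -> SignedNetwork:
    """Assemble RNA-level edges and prune off-path nodes.

    ``interactions`` has columns ``source``, ``target``, ``sign``,
    ``source_db``.  Only rows with both endpoints in ``gene_nodes`` are kept;
    the result is then restricted to nodes lying on at least one directed path
    from an initial node to a final node.  Restriction is node-wise with
    induced edges, which makes the operation idempotent: every node kept is on
    a surviving path, so reachability is unchanged on the induced subgraph.
    """
    gene_nodes = frozenset(gene_nodes)
    if not frozenset(initial_nodes) <= gene_nodes or not frozenset(final_nodes) <= gene_nodes:
        raise ValueError("initial and final nodes must be subsets of the gene-node set")

    rows = interactions[
        interactions["source"].isin(gene_nodes) & interactions["target"].isin(gene_nodes)
    ]
    g = nx.DiGraph()
    g.add_nodes_from(gene_nodes)
    g.add_edges_from(zip(rows["source"], rows["target"]))

    downstream: set[str] = set()
    for n in initial_nodes:
        downstream |= nx.descendants(g, n) | {n}
    upstream: set[str] = set()
    for n in final_nodes:
        upstream |= nx.ancestors(g, n) | {n}
    keep = downstream & upstream
    if not keep:
        warnings.warn("no directed path from any initial node to any final node")

    edges: list[Edge] = []
    seen: set[Edge] = set()
    for src, tgt, sign in zip(rows["source"], rows["target"], rows["sign"]):
        e = (src, tgt, int(sign))
        if src in keep and tgt in keep and e not in seen:
            seen.add(e)
            edges.append(e)
    return SignedNetwork(nodes=frozenset(keep), edges=tuple(edges))


def build_msiren(
    signal_net: SignedNetwork,
    nodes: list[ProteinNode],
    mapping: pd.DataFrame,
    annotations: pd.DataFrame,
    interactions: pd.DataFrame,
    selected_pathways: set[str],
    initial_nodes: frozenset[str] = DEFAULT_INITIAL_NODES,
    final_nodes: frozenset[str] = DEFAULT_FINAL_NODES,
    droppable: frozenset[str] = frozenset(),
) -> SignedNetwork:
    """Run the full three-step pipeline: expand, annotate-filter, re-wire.

    Pathway filtering is applied before interaction matching, following the
    order of the construction steps; initial/final nodes are whitelisted
    through the filter.  Initial and final nodes absent from the expanded
    gene set are ignored (a curated network need not contain every default
    stimulus).
    """
    gene_net = expand_protein_nodes(signal_net, nodes, mapping, droppable=droppable)
    whitelist = (initial_nodes | final_nodes) & gene_net.nodes
    filtered = filter_by_pathway_annotation(
        gene_net, annotations, selected_pathways, whitelist=whitelist
    )
    return infer_rna_edges(
        filtered.nodes,
        interactions,
        initial_nodes & filtered.nodes,
        final_nodes & filtered.nodes,
    )
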