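"""Typed herb-compound-target networks, degree statistics, and exports.

The network is tripartite: herb nodes connect to the compounds they contain,
and compounds connect to the protein targets (gene symbols) they act on.
Herb-target and same-type edges are forbidden.  Degree is the only centrality
used: "main components" are the compounds whose degree strictly exceeds the
mean degree of the compound nodes.

Exports are Cytoscape-compatible: SIF (relations ``contains`` and
``targets``), GraphML with a ``node_type`` attribute, and paired node/edge
TSV tables.  Identical inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["NodeType", "TriNetwork", "DegreeReport", "build_network",
           "degree_report", "export_network", "import_network"]

NodeType = Literal["herb", "compound", "target"]
_VALID_TYPES = ("herb", "compound", "target")
_RELATIONS = {("herb", "compound"): "contains", ("compound", "target"): "targets"}


@dataclass
class TriNetwork:
    """Undirected tripartite graph over herb, compound and target nodes."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        for node, data in g.nodes(data=True):
            if data.get("node_type") not in _VALID_TYPES:
                raise ValueError(f"node {node!r} has invalid type {data.get('node_type')!r}")
        for u, v in g.edges():
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            kinds = {g.nodes[u]["node_type"], g.nodes[v]["node_type"]}
            if kinds not in ({"herb", "compound"}, {"compound", "target"}):
                raise ValueError(
                    f"edge {u!r}-{v!r} violates the herb-compound / "
                    f"compound-target typing ({sorted(kinds)})"
                )

    def node_type(self, node: str) -> NodeType:
        return self.graph.nodes[node]["node_type"]

    def nodes_of(self, node_type: NodeType) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type}

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        """Canonical (sorted-pair) edge set, for comparisons."""
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def induced(self, nodes: Iterable[str]) -> "TriNetwork":
        return TriNetwork(graph=nx.Graph(self.graph.subgraph(set(nodes)).copy()))


@dataclass
class DegreeReport:
    """Nodes of one type ranked by degree (descending, ties by id)."""

    ranked: list[tuple[str, int]]
    mean_degree: float

    def above_mean(self) -> list[tuple[str, int]]:
        """Nodes whose degree strictly exceeds the subset mean."""
        return [(n, d) for n, d in self.ranked if d > self.mean_degree]


def _add_typed_node(g: nx.Graph, node: str, node_type: NodeType) -> None:
    if node in g and g.nodes[node]["node_type"] != node_type:
        raise ValueError(
            f"node id {node!r} used with two types: "
            f"{g.nodes[node]['node_type']!r} and {node_type!r}"
        )
    g.add_node(node, node_type=node_type)


def build_network(
    herb_membership: Mapping[str, Iterable[str]],
    target_pairs: Iterable[tuple[str, str]],
    shared_targets: Iterable[str] | None = None,
) -> TriNetwork:
    """Build the herb-compound-target network.

    Parameters
    ----------
    herb_membership
        Mapping compound_id -> herbs containing it (the screened universe).
    target_pairs
        (compound_id, gene_symbol) pairs from the compound-target mapping.
    shared_targets
        When given, only targets in this set (typically the drug-disease
        intersection) produce edges.  Compounds left without any surviving
        target edge are dropped entirely, along with herbs left empty.
    """
    keep = None if shared_targets is None else set(shared_targets)
    g = nx.Graph()
    surviving: dict[str, set[str]] = {}
    for compound, gene in target_pairs:
        if compound not in herb_membership:
            raise ValueError(f"compound {compound!r} in target map but not in any herb")
        if keep is None or gene in keep:
            surviving.setdefault(compound, set()).add(gene)
    for compound, genes in surviving.items():
        _add_typed_node(g, compound, "compound")
        for herb in herb_membership[compound]:
            _add_typed_node(g, herb, "herb")
            g.add_edge(herb, compound)
        for gene in genes:
            _add_typed_node(g, gene, "target")
            g.add_edge(compound, gene)
    return TriNetwork(graph=g)


def degree_report(net: TriNetwork, subset: NodeType = "compound") -> DegreeReport:
    """Rank nodes of one type by degree and report the subset's mean degree.

    The mean is computed over the chosen subset only; with the default
    ``compound`` subset this compares compounds against each other, which is
    how "main components" are picked.
    """
    nodes = net.nodes_of(subset)
    if not nodes:
        raise ValueError(f"network has no {subset!r} nodes")
    degrees = {n: net.degree(n) for n in nodes}
    ranked = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    mean = sum(degrees.values()) / len(degrees)
    return DegreeReport(ranked=ranked, mean_degree=mean)


# ---------------------------------------------------------------------------
# export / import

def _sorted_edges(net: TriNetwork) -> list[tuple[str, str, str]]:
    """Edges as (source, relation, target) with herb/compound first, sorted."""
    rows = []
    for u, v in net.graph.edges():
        tu, tv = net.node_type(u), net.node_type(v)
        if (tu, tv) not in _RELATIONS:
            u, v, tu, tv = v, u, tv, tu
        rows.append((u, _RELATIONS[(tu, tv)], v))
    return sorted(rows)


def export_network(
    net: TriNetwork,
    path: str | Path,
    format: str = "sif",
) -> list[Path]:
    """Write the network as ``sif``, ``graphml`` or paired node/edge ``tables``.

    Returns the written file paths.  ``tables`` writes ``<path>.nodes.tsv``
    (node_id, node_type, degree) and ``<path>.edges.tsv`` (source, relation,
    target).
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for u, rel, v in _sorted_edges(net):
                fh.write(f"{u}\t{rel}\t{v}\n")
        return [path]
    if format == "graphml":
        g = nx.Graph()
        for node in sorted(net.graph.nodes):
            g.add_node(node, node_type=net.node_type(node))
        for u, rel, v in _sorted_edges(net):
            g.add_edge(u, v, relation=rel)
        nx.write_graphml(g, path, named_key_ids=True)
        return [path]
    if format == "tables":
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        edges_path = path.with_suffix(path.suffix + ".edges.tsv")
        with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("node_id\tnode_type\tdegree\n")
            for node in sorted(net.graph.nodes):
                fh.write(f"{node}\t{net.node_type(node)}\t{net.degree(node)}\n")
        with open(edges_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\trelation\ttarget\n")
            for u, rel, v in _sorted_edges(net):
                fh.write(f"{u}\t{rel}\t{v}\n")
        return [nodes_path, edges_path]
    raise ValueError(f"unknown export format {format!r} (expected sif, graphml or tables)")


def import_network(path: str | Path, format: str = "sif") -> TriNetwork:
    """Re-read a network written by :func:`export_network`."""
    path = Path(path)
    if format == "sif":
        g = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs 3 fields")
                u, rel, v = parts
                try:
                    tu, tv = next(k for k, r in _RELATIONS.items() if r == rel)
                except StopIteration:
                    raise ValueError(f"{path}:{lineno}: unknown relation {rel!r}") from None
                _add_typed_node(g, u, tu)
                _add_typed_node(g, v, tv)
                g.add_edge(u, v)
        return TriNetwork(graph=g)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        for node, data in raw.nodes(data=True):
            _add_typed_node(g, str(node), data["node_type"])
        g.add_edges_from((str(u), str(v)) for u, v in raw.edges())
        return TriNetwork(graph=g)
    raise ValueError(f"unknown import format {format!r} (expected sif or graphml)")
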