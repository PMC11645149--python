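"""Seed-expanded protein-protein interaction network with borrowed and
intrinsic layers, and the inter-layer hypergeometric connectivity test.

A network is grown from a seed gene set by keeping every node within
``hops`` interaction steps of a seed through edges at or above a confidence
cutoff (default one hop: seeds plus first neighbors, STRING medium
confidence 0.4). Gene sets are then projected onto the network as *layers*;
a layer's footprint is the closed neighborhood of its tagged nodes (members
plus their direct interactors). Connectivity between two layers is the
upper-tail hypergeometric probability of their footprints' overlap within
the network universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from cocultnet.io import EdgeTable, GeneSet, write_tsv
from cocultnet.stats import hypergeom_upper_tail

LAYERS = ("borrowed", "intrinsic")


@dataclass
class LayerOverlapTest:
    """Result of a hypergeometric overlap test between two node sets."""

    universe_n: int
    layer1_k: int
    layer2_n: int
    overlap_k: int
    p_value: float
    tail: str = "upper"


@dataclass
class MultilayerNetwork:
    """Undirected PPI graph with per-node layer tags and seed flags.

    Node attributes: ``layers`` (set of layer names), ``seed`` (bool),
    ``isolated_seed`` (seed absent from the edge table). Edge attribute:
    ``confidence``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def layer_members(self, layer: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if layer in d["layers"]}

    def layer_neighborhood(self, layer: str) -> set[str]:
        """Closed neighborhood of the layer: members plus direct interactors."""
        members = self.layer_members(layer)
        hood = set(members)
        for n in members:
            hood.update(self.graph.neighbors(n))
        return hood

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in sorted(self.graph.nodes(data=True)):
            layers = sorted(d["layers"])
            tag = "both" if len(layers) == 2 else (layers[0] if layers else "connector")
            rows.append({"node": n, "layer": tag, "is_seed": d["seed"]})
        return pd.DataFrame(rows, columns=["node", "layer", "is_seed"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": min(a, b), "node_b": max(a, b), "confidence": d["confidence"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
        return df.sort_values(["node_a", "node_b"], ignore_index=True)


def build_seed_network(
    seeds: GeneSet,
    edges: EdgeTable,
    min_confidence: float = 0.4,
    hops: int = 1,
) -> MultilayerNetwork:
    """Grow the PPI network: seeds plus every node within ``hops`` steps of
    a seed via edges with confidence >= ``min_confidence``; keep all
    qualifying edges among retained nodes. Seeds absent from the edge table
    are kept as isolated, flagged nodes."""
    if not seeds.genes:
        raise ValueError("seed gene set is empty")
    if hops < 0:
        raise ValueError("hops must be >= 0")
    kept = edges.filter_confidence(min_confidence)
    full = nx.Graph()
    for _, row in kept.edges.iterrows():
        full.add_edge(row["node_a"], row["node_b"], confidence=float(row["confidence"]))

    frontier = {g for g in seeds.genes if g in full}
    retained = set(frontier)
    for _ in range(hops):
        frontier = {nb for n in frontier for nb in full.neighbors(n)} - retained
        retained |= frontier

    g = full.subgraph(retained).copy()
    for n in g.nodes:
        g.nodes[n]["seed"] = n in seeds.genes
        g.nodes[n]["isolated_seed"] = False
        g.nodes[n]["layers"] = set()
    for s in seeds.genes - set(g.nodes):
        g.add_node(s, seed=True, isolated_seed=True, layers=set())
    return MultilayerNetwork(g)


def project_layer(
    net: MultilayerNetwork, gene_set: GeneSet, layer_name: str
) -> tuple[MultilayerNetwork, dict]:
    """Tag network nodes in ``gene_set`` with ``layer_name``; nodes tagged by
    both layers end up 'both'. Returns the (mutated) network and a report
    with the layer's induced-subgraph node/edge counts."""
    if layer_name not in LAYERS:
        raise ValueError(f"unknown layer {layer_name!r}; expected one of {LAYERS}")
    members = net.nodes & gene_set.genes
    for n in members:
        net.graph.nodes[n]["layers"].add(layer_name)
    sub = net.graph.subgraph(members)
    report = {
        "layer": layer_name,
        "tagged_nodes": len(members),
        "subgraph_edges": sub.number_of_edges(),
    }
    return net, report


def layer_connectivity_test(net: MultilayerNetwork) -> LayerOverlapTest:
    """Hypergeometric test of the overlap between the closed neighborhoods of
    the borrowed and intrinsic layers, within the universe of all network
    nodes. Upper tail: P(X >= observed overlap)."""
    for layer in LAYERS:
        if not net.layer_members(layer):
            raise ValueError(f"layer {layer!r} has no tagged nodes; project it first")
    universe = net.n_nodes()
    hood1 = net.layer_neighborhood("borrowed")
    hood2 = net.layer_neighborhood("intrinsic")
    overlap = len(hood1 & hood2)
    p = hypergeom_upper_tail(universe, len(hood1), len(hood2), overlap)
    return LayerOverlapTest(universe, len(hood1), len(hood2), overlap, p)


def export_network(net: MultilayerNetwork, outdir: str | Path, prefix: str = "network") -> dict:
    """Write node and edge TSVs plus a summary JSON; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = net.node_table()
    edges = net.edge_table()
    write_tsv(nodes, outdir / f"{prefix}_nodes.tsv")
    write_tsv(edges, outdir / f"{prefix}_edges.tsv")
    summary = {
        "n_nodes": int(len(nodes)),
        "n_edges": int(len(edges)),
        "n_seeds": int(nodes["is_seed"].sum()),
        "layer_borrowed": len(net.layer_members("borrowed")),
        "layer_intrinsic": len(net.layer_members("intrinsic")),
        "layer_both": int((nodes["layer"] == "both").sum()),
    }
    (outdir / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def import_network(outdir: str | Path, prefix: str = "network") -> MultilayerNetwork:
    """Inverse of :func:`export_network` (round-trips node tags and edges)."""
    outdir = Path(outdir)
    nodes = pd.read_csv(outdir / f"{prefix}_nodes.tsv", sep="\t")
    edges = pd.read_csv(outdir / f"{prefix}_edges.tsv", sep="\t")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        tag = row["layer"]
        layers = set(LAYERS) if tag == "both" else ({tag} if tag in LAYERS else set())
        g.add_node(row["node"], seed=bool(row["is_seed"]), isolated_seed=False, layers=layers)
    for _, row in edges.iterrows():
        g.add_edge(row["node_a"], row["node_b"], confidence=float(row["confidence"]))
    for n in g.nodes:  # edges may add endpoints missing from the node list
        g.nodes[n].setdefault("seed", False)
        g.nodes[n].setdefault("isolated_seed", False)
        g.nodes[n].setdefault("layers", set())
    return MultilayerNetwork(g)
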