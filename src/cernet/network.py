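"""Tripartite ceRNA network assembly and hub calling.

Nodes are the lncRNAs and mRNAs of final ceRNA pairs plus their shared
(witness) miRNAs; edges carry the Spearman correlation and a regulation
attribute (the DE direction of the regulated, non-miRNA endpoint).  A node
is a hub when its degree strictly exceeds the arithmetic mean degree of the
entire network — so regular graphs have no hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

EDGE_TYPES = ("lncRNA-miRNA", "miRNA-mRNA", "lncRNA-mRNA")


@dataclass
class CeRNANetwork:
    """A validated tripartite lncRNA-miRNA-mRNA graph.

    Node attributes: ``node_class`` (mRNA/miRNA/lncRNA) and ``direction``
    (up/down).  Edge attributes: ``edge_type``, ``scc``, ``regulation``.
    """

    graph: nx.Graph

    @property
    def degrees(self) -> dict:
        return dict(self.graph.degree())

    @property
    def mean_degree(self) -> float:
        n = self.graph.number_of_nodes()
        return 2 * self.graph.number_of_edges() / n if n else 0.0

    @property
    def hubs(self) -> set:
        mean = self.mean_degree
        return {v for v, d in self.graph.degree() if d > mean}

    def validate(self) -> None:
        g = self.graph
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()
        for u, v, attrs in g.edges(data=True):
            if attrs["edge_type"] != "lncRNA-mRNA":
                continue
            lnc, mrna = (u, v) if g.nodes[u]["node_class"] == "lncRNA" else (v, u)
            witnessed = any(
                g.nodes[w]["node_class"] == "miRNA"
                and g.has_edge(lnc, w)
                and g.has_edge(w, mrna)
                for w in g.neighbors(lnc)
            )
            if not witnessed:
                raise ValueError(f"lncRNA-mRNA edge {lnc}-{mrna} lacks a witnessing miRNA")


def _direction_index(de: dict[str, pd.DataFrame]) -> dict:
    idx = {}
    for cls, table in de.items():
        for fid, direction in table[["feature_id", "direction"]].itertuples(index=False):
            idx[fid] = (cls, direction)
    return idx


def build_network(
    final_pairs: pd.DataFrame,
    passing_pairs: pd.DataFrame,
    de: dict[str, pd.DataFrame],
    include_lnc_mrna_edges: bool = True,
) -> CeRNANetwork:
    """Assemble the network from final ceRNA pairs and their witness edges.

    ``final_pairs`` is :func:`cernet.cerna.score_pairs` output (rows with
    ``final``); ``passing_pairs`` supplies the miRNA edge correlations.  A
    feature without a DE record is a hard error (pipeline ordering bug).
    Edge ``regulation`` is the DE direction of the non-miRNA endpoint, and
    of the mRNA for lncRNA-mRNA edges.
    """
    directions = _direction_index(de)
    scc_lookup = {
        (a, b): s for a, b, s in passing_pairs[["a_id", "b_id", "scc"]].itertuples(index=False)
    }
    g = nx.Graph()

    def add_node(fid: str, cls: str) -> None:
        if fid not in directions:
            raise KeyError(f"feature {fid} has no DE record")
        de_cls, direction = directions[fid]
        if de_cls != cls:
            raise ValueError(f"feature {fid} is recorded as {de_cls}, expected {cls}")
        g.add_node(fid, node_class=cls, direction=direction)

    final = final_pairs[final_pairs["final"]] if "final" in final_pairs else final_pairs
    for row in final.itertuples(index=False):
        lnc, mrna, shared = row.lncrna_id, row.mrna_id, row.shared_mirnas
        add_node(lnc, "lncRNA")
        add_node(mrna, "mRNA")
        for mi in shared:
            add_node(mi, "miRNA")
            g.add_edge(
                lnc,
                mi,
                edge_type="lncRNA-miRNA",
                scc=scc_lookup.get((lnc, mi)),
                regulation=g.nodes[lnc]["direction"],
            )
            g.add_edge(
                mi,
                mrna,
                edge_type="miRNA-mRNA",
                scc=scc_lookup.get((mi, mrna)),
                regulation=g.nodes[mrna]["direction"],
            )
        if include_lnc_mrna_edges:
            g.add_edge(
                lnc,
                mrna,
                edge_type="lncRNA-mRNA",
                scc=row.scc,
                regulation=g.nodes[mrna]["direction"],
            )
    net = CeRNANetwork(g)
    net.validate()
    return net


def hub_nodes(net: CeRNANetwork) -> set:
    """Nodes whose degree strictly exceeds the network-wide mean degree."""
    return net.hubs


def network_report(net: CeRNANetwork) -> dict:
    """Summary counts: nodes per class, edges per type, degrees, hubs."""
    g = net.graph
    nodes_per_class = {cls: 0 for cls in ("mRNA", "miRNA", "lncRNA")}
    for _, attrs in g.nodes(data=True):
        nodes_per_class[attrs["node_class"]] += 1
    edges_per_type = {et: 0 for et in EDGE_TYPES}
    for _, _, attrs in g.edges(data=True):
        edges_per_type[attrs["edge_type"]] += 1
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "nodes_per_class": nodes_per_class,
        "edges_per_type": edges_per_type,
        "mean_degree": net.mean_degree,
        "hubs": sorted(net.hubs),
    }
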