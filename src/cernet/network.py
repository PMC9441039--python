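"""Tripartite ceRNA network assembly, subnetwork extraction, and export.

Nodes are typed (mRNA, lncRNA, miRNA) and edges connect only permitted type
pairs: lncRNA-miRNA and miRNA-mRNA interaction edges, plus explicit
lncRNA-mRNA competing-pair edges carrying the pair statistics.  Exports are
Cytoscape-readable (SIF, GraphML, edge TSV); the conventional node shapes
(circle = mRNA, triangle = miRNA, diamond = lncRNA) travel as a node
attribute.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cerna import CeRNAPair
from .targets import TargetInteraction

NODE_SHAPES = {"mRNA": "circle", "miRNA": "triangle", "lncRNA": "diamond"}
EDGE_RELATIONS = {
    ("lncRNA", "miRNA"): "lnc_mi",
    ("miRNA", "mRNA"): "mi_m",
    ("lncRNA", "mRNA"): "ceRNA",
}


def _validate(net: nx.Graph) -> None:
    for node, data in net.nodes(data=True):
        if data.get("type") not in NODE_SHAPES:
            raise ValueError(f"node {node!r} has invalid type {data.get('type')!r}")
    for u, v, data in net.edges(data=True):
        tu, tv = net.nodes[u]["type"], net.nodes[v]["type"]
        pair = (tu, tv) if (tu, tv) in EDGE_RELATIONS else (tv, tu)
        if pair not in EDGE_RELATIONS:
            raise ValueError(f"forbidden edge type {tu}-{tv} ({u}, {v})")
        if data.get("relation") != EDGE_RELATIONS[pair]:
            raise ValueError(f"edge ({u}, {v}) mislabelled: {data.get('relation')}")


def build_network(
    pairs: Sequence[CeRNAPair],
    interactions: Sequence[TargetInteraction],
    de_calls: Mapping[str, str] | None = None,
    params: Mapping | None = None,
) -> nx.Graph:
    """Assemble the tripartite graph from passing competing pairs.

    For every passing pair the lncRNA, mRNA and all shared miRNAs become
    nodes; each shared miRNA contributes its two interaction edges and the
    pair contributes one competing-pair edge annotated with its statistics.
    Threshold provenance is stored in ``net.graph['params']``.
    """
    de_calls = de_calls or {}
    known = {(it.mirna_id, it.transcript_id) for it in interactions}
    net = nx.Graph()
    net.graph["params"] = dict(params or {})

    def _add_node(nid: str, ntype: str) -> None:
        net.add_node(
            nid,
            type=ntype,
            shape=NODE_SHAPES[ntype],
            de_call=de_calls.get(nid, "unknown"),
        )

    for p in sorted(pairs, key=lambda p: (p.lncrna_id, p.mrna_id)):
        if not p.passed:
            continue
        _add_node(p.lncrna_id, "lncRNA")
        _add_node(p.mrna_id, "mRNA")
        for mi in p.shared_mirnas:
            if (mi, p.lncrna_id) not in known or (mi, p.mrna_id) not in known:
                raise ValueError(
                    f"pair ({p.lncrna_id}, {p.mrna_id}) references miRNA {mi} "
                    "without both interactions"
                )
            _add_node(mi, "miRNA")
            net.add_edge(p.lncrna_id, mi, relation="lnc_mi")
            net.add_edge(mi, p.mrna_id, relation="mi_m")
        net.add_edge(
            p.lncrna_id,
            p.mrna_id,
            relation="ceRNA",
            hypergeom_p=p.hypergeom_p,
            hypergeom_fdr=p.hypergeom_fdr,
            pearson_r=p.pearson_r,
            n_shared=len(p.shared_mirnas),
        )
    _validate(net)
    return net


def network_summary(net: nx.Graph) -> dict:
    """Counts of nodes and edges by type, JSON-serializable."""
    node_counts = {t: 0 for t in NODE_SHAPES}
    for _, d in net.nodes(data=True):
        node_counts[d["type"]] += 1
    edge_counts = {r: 0 for r in EDGE_RELATIONS.values()}
    for _, _, d in net.edges(data=True):
        edge_counts[d["relation"]] += 1
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "nodes_by_type": node_counts,
        "edges_by_relation": edge_counts,
    }


def extract_subnetwork(net: nx.Graph, focus_id: str, radius: int = 1) -> nx.Graph:
    """Induced subgraph of a focus node and its neighbours within ``radius``.

    The returned graph reports, in ``graph['focus']``, the focus id and the
    number of miRNAs and lncRNAs adjacent to it (the counts quoted for
    gene-centred subnetworks).
    """
    if focus_id not in net:
        raise KeyError(f"unknown focus node {focus_id!r}")
    nodes = {focus_id}
    frontier = {focus_id}
    for _ in range(radius):
        frontier = {nb for n in frontier for nb in net.neighbors(n)} - nodes
        nodes |= frontier
    sub = net.subgraph(nodes).copy()
    sub.graph["focus"] = {
        "id": focus_id,
        "n_mirna_neighbors": sum(
            1 for nb in net.neighbors(focus_id) if net.nodes[nb]["type"] == "miRNA"
        ),
        "n_lncrna_neighbors": sum(
            1 for nb in net.neighbors(focus_id) if net.nodes[nb]["type"] == "lncRNA"
        ),
    }
    return sub


def export_network(net: nx.Graph, path: str | Path, fmt: str = "SIF") -> None:
    """Write the network as SIF, GraphML, or an edge-attribute TSV."""
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{d['relation']}\t{v}\n")
    elif fmt == "GRAPHML":
        out = nx.Graph()
        out.graph.update({"params": json.dumps(net.graph.get("params", {}))})
        for n, d in net.nodes(data=True):
            out.add_node(n, **d)
        for u, v, d in net.edges(data=True):
            out.add_edge(u, v, **d)
        nx.write_graphml(out, path)
    elif fmt in ("TSV", "EDGE-TSV"):
        with open(path, "w") as fh:
            fh.write("source\trelation\ttarget\thypergeom_p\tpearson_r\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(
                    f"{u}\t{d['relation']}\t{v}"
                    f"\t{d.get('hypergeom_p', '')}\t{d.get('pearson_r', '')}\n"
                )
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def read_graphml(path: str | Path) -> nx.Graph:
    net = nx.read_graphml(path)
    net = nx.relabel_nodes(net, str)
    if "params" in net.graph and isinstance(net.graph["params"], str):
        net.graph["params"] = json.loads(net.graph["params"])
    _validate(net)
    return net
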