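"""miRNA-TF-gene regulatory networks: assembly, motifs, hubs, sub-networks.

Nodes are typed (miRNA, TF, gene — disjoint: an id in the TF list is typed
TF, never gene) and edges are typed by their regulator
(``miRNA_repression`` from a miRNA, ``TF_regulation`` from a TF).  The
motif vocabulary is the classic co-regulatory one:

* miRNA-FFL: miRNA represses a TF and a gene, and the TF regulates the
  same gene (edges m->t, m->g, t->g);
* TF-FFL: TF regulates a miRNA and a gene, and the miRNA represses the
  same gene (edges t->m, t->g, m->g);
* composite FBL: mutual miRNA<->TF regulation (m->t and t->m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES = ("miRNA", "TF", "gene")
EDGE_KIND = {"miRNA": "miRNA_repression", "TF": "TF_regulation"}

MIRNA_FFL = "miRNA_FFL"
TF_FFL = "TF_FFL"
COMPOSITE_FBL = "composite_FBL"


@dataclass
class FflMotif:
    motif_type: str
    members: tuple[str, ...]  # (miRNA, TF, gene) for FFLs; (miRNA, TF) for FBLs


@dataclass
class RegulatoryNetwork:
    """Typed directed regulatory graph for one condition."""

    graph: nx.DiGraph
    condition: str | None = None

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("node_type") not in NODE_TYPES:
                raise ValueError(f"node {node!r} has unknown type "
                                 f"{data.get('node_type')!r}")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            src_type = self.graph.nodes[u]["node_type"]
            if src_type == "gene":
                raise ValueError(f"gene {u!r} cannot be a regulator")
            if data.get("edge_kind") != EDGE_KIND[src_type]:
                raise ValueError(f"edge {u}->{v} kind mismatch")

    # -- counts ------------------------------------------------------------

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["node_type"] == node_type)

    def summary(self) -> dict[str, int]:
        return {
            "n_mirna": len(self.nodes_of_type("miRNA")),
            "n_tf": len(self.nodes_of_type("TF")),
            "n_gene": len(self.nodes_of_type("gene")),
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
        }


def build_network(condition_genes: list[str], dem_list: list[str],
                  tf_list: list[str], edges: pd.DataFrame,
                  de_calls: dict[str, str] | None = None,
                  stable_flags: dict[str, str] | None = None,
                  condition: str | None = None) -> RegulatoryNetwork:
    """Assemble the condition network from a typed edge table.

    Candidate nodes are the differentially expressed miRNAs plus the
    condition gene set (ids in ``tf_list`` typed TF); edges from the table
    are kept when both endpoints are candidates, and nodes left isolated
    are dropped.  ``de_calls``/``stable_flags`` annotate nodes.
    """
    required = {"source", "target", "source_type", "target_type"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    bad = edges[~edges["source_type"].isin(["miRNA", "TF"])
                | ~edges["target_type"].isin(NODE_TYPES)]
    if len(bad):
        raise ValueError(f"unknown node type in edge rows: "
                         f"{bad.head(3).to_dict('records')}")

    tfs = set(tf_list)
    demset = set(dem_list)
    geneset = set(condition_genes)

    def node_type(ident: str) -> str | None:
        if ident in demset:
            return "miRNA"
        if ident in geneset:
            return "TF" if ident in tfs else "gene"
        return None

    de_calls = de_calls or {}
    stable_flags = stable_flags or {}
    g = nx.DiGraph()
    rows = edges.sort_values(["source", "target"], kind="mergesort")
    for src, tgt, st in zip(rows["source"], rows["target"], rows["source_type"]):
        ts, tt = node_type(src), node_type(tgt)
        if ts is None or tt is None or src == tgt:
            continue
        if ts == "gene":
            continue  # genes do not regulate
        for ident, typ in ((src, ts), (tgt, tt)):
            if ident not in g:
                g.add_node(ident, node_type=typ,
                           de_call=de_calls.get(ident, "ns"),
                           stable=stable_flags.get(ident, ""))
        g.add_edge(src, tgt, edge_kind=EDGE_KIND[ts])
    net = RegulatoryNetwork(g, condition)
    logger.info("built %s network: %s", condition, net.summary())
    return net


def network_from_edges(edges: pd.DataFrame, tf_list: list[str],
                       condition: str | None = None) -> RegulatoryNetwork:
    """Network over every edge-table participant (no DE/gene-set filter)."""
    mirnas = sorted(set(edges.loc[edges["source_type"] == "miRNA", "source"])
                    | set(edges.loc[edges["target_type"] == "miRNA", "target"]))
    genes = sorted((set(edges["source"]) | set(edges["target"]))
                   - set(mirnas))
    return build_network(genes, mirnas, tf_list, edges, condition=condition)


def enumerate_motifs(network: RegulatoryNetwork) -> list[FflMotif]:
    """Exhaustive FFL/FBL enumeration, lexicographically ordered."""
    g = network.graph
    ntype = nx.get_node_attributes(g, "node_type")
    motifs: list[FflMotif] = []

    mirnas = [n for n in g if ntype[n] == "miRNA"]
    for m in mirnas:
        succ_m = list(g.successors(m))
        m_tfs = [t for t in succ_m if ntype[t] == "TF"]
        m_genes = {x for x in succ_m if ntype[x] == "gene"}
        for t in m_tfs:
            # miRNA-FFL: m->t, m->g, t->g
            for gene in m_genes:
                if g.has_edge(t, gene):
                    motifs.append(FflMotif(MIRNA_FFL, (m, t, gene)))
            # TF-FFL: t->m, t->g, m->g
            if g.has_edge(t, m):
                motifs.append(FflMotif(COMPOSITE_FBL, (m, t)))
                for gene in m_genes:
                    if g.has_edge(t, gene):
                        motifs.append(FflMotif(TF_FFL, (m, t, gene)))
        # TF-FFLs where the TF does not also receive an m->t edge
        pred_m = [t for t in g.predecessors(m) if ntype[t] == "TF"
                  and not g.has_edge(m, t)]
        for t in pred_m:
            for gene in m_genes:
                if g.has_edge(t, gene):
                    motifs.append(FflMotif(TF_FFL, (m, t, gene)))
    motifs.sort(key=lambda mo: (mo.motif_type, mo.members))
    return motifs


def motifs_frame(motifs: list[FflMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_type": [m.motif_type for m in motifs],
            "mirna": [m.members[0] for m in motifs],
            "tf": [m.members[1] for m in motifs],
            "gene": [m.members[2] if len(m.members) > 2 else "" for m in motifs],
        }
    )


def degree_and_hubs(network: RegulatoryNetwork,
                    top_fraction: float = 0.05) -> pd.DataFrame:
    """Node degree table with a hub flag for the top fraction (ties kept).

    Sorted by total degree descending then node id.  The hub cutoff is the
    total degree of the ceil(top_fraction * n)-th ranked node; every node
    at or above it is flagged.
    """
    import math

    g = network.graph
    rows = [
        (n, d["node_type"], g.in_degree(n), g.out_degree(n),
         g.in_degree(n) + g.out_degree(n))
        for n, d in g.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node", "node_type", "in_degree",
                                     "out_degree", "total_degree"])
    df = df.sort_values(["total_degree", "node"],
                        ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    if len(df):
        n_top = max(1, math.ceil(top_fraction * len(df)))
        cutoff = df["total_degree"].iloc[n_top - 1]
        df["hub"] = df["total_degree"] >= cutoff
    else:
        df["hub"] = pd.Series(dtype=bool)
    return df


def extract_core_subnetwork(network: RegulatoryNetwork,
                            pathway_hits: list[str]) -> RegulatoryNetwork:
    """Induced sub-network around pathway-annotated and DE nodes.

    Keeps differentially expressed nodes, pathway-hit genes, and the
    direct regulators of either; induces the parent network on that node
    set and drops isolated nodes.
    """
    g = network.graph
    keep = {n for n, d in g.nodes(data=True) if d.get("de_call") in ("up", "down")}
    keep |= {n for n in pathway_hits if n in g}
    regulators = {u for n in keep for u in g.predecessors(n)}
    keep |= regulators
    sub = g.subgraph(keep).copy()
    sub.remove_nodes_from([n for n in list(sub) if sub.degree(n) == 0])
    return RegulatoryNetwork(sub, network.condition)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_sif(network: RegulatoryNetwork, path: str | Path) -> None:
    lines = [f"{u}\t{d['edge_kind']}\t{v}"
             for u, v, d in sorted(network.graph.edges(data=True))]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path: str | Path, tf_list: list[str],
             mirna_prefixes: tuple[str, ...] = ("miR", "hsa-miR", "hsa-let")) -> pd.DataFrame:
    """Read a SIF file back into a typed edge table."""
    tfs = set(tf_list)

    def typ(ident: str) -> str:
        if any(ident.startswith(p) for p in mirna_prefixes):
            return "miRNA"
        return "TF" if ident in tfs else "gene"

    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        u, _, v = line.split("\t")
        rows.append((u, v, typ(u), typ(v)))
    return pd.DataFrame(rows, columns=["source", "target", "source_type",
                                       "target_type"])


def write_graphml(network: RegulatoryNetwork, path: str | Path) -> None:
    # rebuild in sorted order so serialisation is deterministic
    g = nx.DiGraph()
    for n in sorted(network.graph.nodes):
        g.add_node(n, **network.graph.nodes[n])
    for u, v in sorted(network.graph.edges):
        g.add_edge(u, v, **network.graph.edges[u, v])
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> RegulatoryNetwork:
    return RegulatoryNetwork(nx.read_graphml(path))


def node_table(network: RegulatoryNetwork) -> pd.DataFrame:
    rows = [(n, d["node_type"], d.get("de_call", "ns"), d.get("stable", ""))
            for n, d in sorted(network.graph.nodes(data=True))]
    return pd.DataFrame(rows, columns=["node", "node_type", "de_call", "stable"])
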