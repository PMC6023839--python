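"""Regulatory networks: assembly, motif enumeration, hubs, I/O round trips."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from talnet import regnet
from talnet.regnet import (
    COMPOSITE_FBL,
    MIRNA_FFL,
    TF_FFL,
    RegulatoryNetwork,
    build_network,
    degree_and_hubs,
    enumerate_motifs,
    extract_core_subnetwork,
    network_from_edges,
)


def edge_table(rows):
    return pd.DataFrame(rows, columns=["source", "target", "source_type",
                                       "target_type"])


def brute_force_motifs(net: RegulatoryNetwork):
    """Exhaustive typed scan over all (miRNA, TF, gene) triples and
    (miRNA, TF) pairs — the independent oracle."""
    g = net.graph
    ntype = nx.get_node_attributes(g, "node_type")
    mirnas = [n for n in g if ntype[n] == "miRNA"]
    tfs = [n for n in g if ntype[n] == "TF"]
    genes = [n for n in g if ntype[n] == "gene"]
    out = []
    for m, t, x in itertools.product(mirnas, tfs, genes):
        if g.has_edge(m, t) and g.has_edge(m, x) and g.has_edge(t, x):
            out.append((MIRNA_FFL, (m, t, x)))
        if g.has_edge(t, m) and g.has_edge(t, x) and g.has_edge(m, x):
            out.append((TF_FFL, (m, t, x)))
    for m, t in itertools.product(mirnas, tfs):
        if g.has_edge(m, t) and g.has_edge(t, m):
            out.append((COMPOSITE_FBL, (m, t)))
    return sorted(set(out))


def random_typed_network(rng, n_nodes=30, p=0.08):
    n_mir = max(2, n_nodes // 5)
    n_tf = max(2, n_nodes // 5)
    mirnas = [f"miR-{i}" for i in range(n_mir)]
    tfs = [f"TF{i}" for i in range(n_tf)]
    genes = [f"G{i}" for i in range(n_nodes - n_mir - n_tf)]
    rows = []
    for m in mirnas:
        for t in tfs + genes + [x for x in mirnas if x != m]:
            if rng.random() < p:
                tt = "TF" if t in tfs else ("miRNA" if t.startswith("miR")
                                            else "gene")
                rows.append((m, t, "miRNA", tt))
    for t in tfs:
        for x in genes + mirnas + [y for y in tfs if y != t]:
            if rng.random() < p:
                tt = "TF" if x in tfs else ("miRNA" if x.startswith("miR")
                                            else "gene")
                rows.append((t, x, "TF", tt))
    edges = edge_table(rows)
    return build_network(genes + tfs, mirnas, tfs, edges)


class TestBuildNetwork:
    def test_empty_edge_table_gives_empty_network(self):
        net = build_network(["G1"], ["miR-1"], [], edge_table([]))
        assert net.graph.number_of_nodes() == 0

    def test_edges_filtered_by_node_membership(self):
        edges = edge_table([
            ("miR-1", "G1", "miRNA", "gene"),
            ("miR-1", "G9", "miRNA", "gene"),    # G9 not in the gene set
            ("miR-9", "G1", "miRNA", "gene"),    # miR-9 not a DEM
            ("TF1", "G1", "TF", "gene"),
        ])
        net = build_network(["G1", "TF1"], ["miR-1"], ["TF1"], edges)
        assert set(net.graph.edges) == {("miR-1", "G1"), ("TF1", "G1")}
        assert net.graph.nodes["TF1"]["node_type"] == "TF"

    def test_node_types_are_disjoint_and_counts_add_up(self, rng):
        net = random_typed_network(rng, 40)
        s = net.summary()
        assert s["n_mirna"] + s["n_tf"] + s["n_gene"] == s["n_nodes"]

    def test_unknown_node_type_rejected(self):
        edges = pd.DataFrame([("a", "b", "protein", "gene")],
                             columns=["source", "target", "source_type",
                                      "target_type"])
        with pytest.raises(ValueError, match="unknown node type"):
            build_network(["b"], ["a"], [], edges)

    def test_isolated_nodes_dropped(self):
        edges = edge_table([("miR-1", "G1", "miRNA", "gene")])
        net = build_network(["G1", "G2"], ["miR-1", "miR-2"], [], edges)
        assert set(net.graph.nodes) == {"miR-1", "G1"}


class TestMotifs:
    def test_minimal_mirna_ffl(self):
        edges = edge_table([("m", "t", "miRNA", "TF"),
                            ("m", "g", "miRNA", "gene"),
                            ("t", "g", "TF", "gene")])
        net = build_network(["g", "t"], ["m"], ["t"], edges)
        motifs = enumerate_motifs(net)
        assert [(x.motif_type, x.members) for x in motifs] == \
            [(MIRNA_FFL, ("m", "t", "g"))]

    def test_minimal_tf_ffl_and_fbl(self):
        edges = edge_table([("t", "m", "TF", "miRNA"),
                            ("t", "g", "TF", "gene"),
                            ("m", "g", "miRNA", "gene"),
                            ("m", "t", "miRNA", "TF")])
        net = build_network(["g", "t"], ["m"], ["t"], edges)
        kinds = [(x.motif_type, x.members) for x in enumerate_motifs(net)]
        assert (TF_FFL, ("m", "t", "g")) in kinds
        assert (MIRNA_FFL, ("m", "t", "g")) in kinds
        assert (COMPOSITE_FBL, ("m", "t")) in kinds

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(60):
            net = random_typed_network(rng, int(rng.integers(15, 50)))
            got = sorted((x.motif_type, x.members)
                         for x in enumerate_motifs(net))
            assert got == brute_force_motifs(net)

    def test_invariant_to_relabeling(self, rng):
        net = random_typed_network(rng, 35)
        counts = {}
        for x in enumerate_motifs(net):
            counts[x.motif_type] = counts.get(x.motif_type, 0) + 1
        # relabel nodes (permute indices within each type)
        mapping = {}
        for prefix in ("miR-", "TF", "G"):
            nodes = sorted(n for n in net.graph if n.startswith(prefix))
            perm = list(rng.permutation(nodes))
            mapping.update(dict(zip(nodes, perm)))
        g2 = nx.relabel_nodes(net.graph, mapping)
        counts2 = {}
        for x in enumerate_motifs(RegulatoryNetwork(g2)):
            counts2[x.motif_type] = counts2.get(x.motif_type, 0) + 1
        assert counts == counts2


class TestDegreesAndHubs:
    def test_star_degrees(self):
        edges = edge_table([("TF1", f"G{i}", "TF", "gene") for i in range(10)])
        net = build_network([f"G{i}" for i in range(10)] + ["TF1"], [],
                            ["TF1"], edges)
        table = degree_and_hubs(net)
        assert table.iloc[0]["node"] == "TF1"
        assert table.iloc[0]["total_degree"] == 10
        assert set(table["total_degree"][1:]) == {1}
        assert table["hub"].sum() == 1

    def test_handshake_identity(self, rng):
        net = random_typed_network(rng, 40)
        table = degree_and_hubs(net)
        assert table["out_degree"].sum() == net.graph.number_of_edges()
        assert table["in_degree"].sum() == net.graph.number_of_edges()

    def test_hub_set_equals_sort_oracle_with_ties(self, rng):
        net = random_typed_network(rng, 45)
        table = degree_and_hubs(net, top_fraction=0.1)
        import math
        n_top = max(1, math.ceil(0.1 * len(table)))
        cutoff = sorted(table["total_degree"], reverse=True)[n_top - 1]
        expected = set(table.loc[table["total_degree"] >= cutoff, "node"])
        assert set(table.loc[table["hub"], "node"]) == expected


class TestCoreSubnetwork:
    def _net(self):
        edges = edge_table([
            ("miR-1", "G1", "miRNA", "gene"),
            ("miR-1", "G2", "miRNA", "gene"),
            ("TF1", "G2", "TF", "gene"),
            ("TF1", "G3", "TF", "gene"),
        ])
        return build_network(["G1", "G2", "G3", "TF1"], ["miR-1"], ["TF1"],
                             edges, de_calls={"miR-1": "up", "G1": "down"})

    def test_full_hit_list_is_idempotent(self):
        net = self._net()
        core = extract_core_subnetwork(net, ["G1", "G2", "G3"])
        assert set(core.graph.edges) == set(net.graph.edges)

    def test_edges_are_subset_of_parent(self):
        net = self._net()
        core = extract_core_subnetwork(net, ["G2"])
        assert set(core.graph.edges) <= set(net.graph.edges)
        # G3 is neither DE nor a pathway hit nor a regulator -> dropped
        assert "G3" not in core.graph

    def test_empty_hits_keeps_de_nodes_and_regulators(self):
        net = self._net()
        core = extract_core_subnetwork(net, [])
        assert "miR-1" in core.graph and "G1" in core.graph


class TestIO:
    def test_sif_round_trip_preserves_network(self, rng, tmp_path):
        net = random_typed_network(rng, 30)
        path = tmp_path / "n.sif"
        regnet.write_sif(net, path)
        edges2 = regnet.read_sif(path, tf_list=[n for n in net.graph
                                                if n.startswith("TF")])
        net2 = network_from_edges(edges2, [n for n in net.graph
                                           if n.startswith("TF")])
        assert set(net2.graph.edges) == set(net.graph.edges)
        assert nx.get_node_attributes(net2.graph, "node_type") == \
            nx.get_node_attributes(net.graph, "node_type")

    def test_graphml_round_trip_preserves_attributes(self, rng, tmp_path):
        net = random_typed_network(rng, 25)
        path = tmp_path / "n.graphml"
        regnet.write_graphml(net, path)
        net2 = regnet.read_graphml(path)
        assert set(net2.graph.edges) == set(net.graph.edges)
        assert nx.get_node_attributes(net2.graph, "node_type") == \
            nx.get_node_attributes(net.graph, "node_type")
        assert nx.get_edge_attributes(net2.graph, "edge_kind") == \
            nx.get_edge_attributes(net.graph, "edge_kind")

    def test_planted_ffls_recovered_from_written_dataset(self, default_dataset):
        edges = pd.read_csv(default_dataset["paths"]["edges"], sep="\t",
                            dtype=str)
        tf_list = [x.strip() for x in
                   default_dataset["paths"]["tf_list"].read_text().splitlines()
                   if x.strip()]
        net = network_from_edges(edges, tf_list)
        found = {x.members for x in enumerate_motifs(net)
                 if x.motif_type == MIRNA_FFL}
        for ffl in default_dataset["truth"].ffls:
            assert tuple(ffl) in found
        # and the enumeration agrees with the brute-force oracle
        assert sorted((x.motif_type, x.members)
                      for x in enumerate_motifs(net)) == \
            brute_force_motifs(net)
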