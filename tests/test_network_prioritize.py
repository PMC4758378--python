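import networkx as nx
import numpy as np
import pandas as pd
import pytest

from uprhd.consensus import ConsensusSignature
from uprhd.datasets import MOTIF_COLUMNS, load_prioritization_table
from uprhd.network_prioritize import (
    build_interactome,
    cross_annotation,
    overlay_annotation,
    read_edge_list,
    triset_prioritize,
    write_sif,
)
from uprhd.synthetic_data import simulate_network


class TestBuildInteractome:
    def test_no_seed_in_edges_rejected(self):
        with pytest.raises(ValueError, match="no seed"):
            build_interactome([("A", "B"), ("B", "C")], seeds=["XBP1"])

    def test_star_graph(self):
        edges = [("XBP1", f"N{i}") for i in range(5)]
        net = build_interactome(edges, seeds=["XBP1"])
        assert len(net) == 6 and len(net.edges()) == 5

    def test_one_hop_closure_matches_bfs_oracle(self):
        rng = np.random.default_rng(20)
        g = nx.gnm_random_graph(20, 40, seed=4)
        g = nx.relabel_nodes(g, {i: f"P{i}" for i in range(20)})
        seeds = ["P0", "P5"]
        net = build_interactome(list(g.edges), seeds=seeds)
        expected = set(seeds)
        for s in seeds:
            expected |= set(nx.descendants_at_distance(g, s, 1))
        assert net.nodes == expected

    def test_induced_flag_controls_neighbor_edges(self):
        edges = [("XBP1", "A"), ("XBP1", "B"), ("A", "B")]
        assert len(build_interactome(edges, seeds=["XBP1"]).edges()) == 3
        assert len(build_interactome(edges, seeds=["XBP1"], induced=False).edges()) == 2

    def test_idempotent_on_exported_edges(self):
        edges, _, _ = simulate_network(n_nodes=60, n_edges=150, planted_apoptosis_overlap=5,
                                       planted_htt_overlap=2, seed=3)
        net = build_interactome(edges)
        rebuilt = build_interactome(net.edges())
        assert rebuilt.nodes == net.nodes and rebuilt.edges() == net.edges()

    def test_self_loops_discarded(self):
        net = build_interactome([("XBP1", "XBP1"), ("XBP1", "A")], seeds=["XBP1"])
        assert net.edges() == [("A", "XBP1")]


class TestOverlay:
    def test_disjoint_annotation_counts_zero(self):
        net = build_interactome([("XBP1", "A")], seeds=["XBP1"])
        _, count = overlay_annotation(net, {"Q", "R"})
        assert count == 0

    def test_annotation_equal_to_nodes(self):
        net = build_interactome([("XBP1", "A"), ("XBP1", "B")], seeds=["XBP1"])
        table, count = overlay_annotation(net, net.nodes)
        assert count == len(net) and table["annotated"].all()

    def test_planted_overlap_recovered(self):
        edges, annotations, truth = simulate_network(seed=2)
        net = build_interactome(edges)
        _, count = overlay_annotation(net, annotations["apoptosis"])
        assert count == 40
        assert truth.planted_overlaps["apoptosis_in_interactome"] <= net.nodes


class TestCrossAnnotation:
    def test_planted_double_overlap(self):
        edges, annotations, _ = simulate_network(seed=2)
        net = build_interactome(edges)
        cross = cross_annotation(net, annotations["apoptosis"],
                                 {g: "indirect" for g in annotations["htt_interactors"]})
        assert len(cross) == 6

    def test_empty_first_annotation(self):
        net = build_interactome([("XBP1", "A")], seeds=["XBP1"])
        assert cross_annotation(net, set(), {"A": "direct"}).empty

    def test_all_direct_typing(self):
        net = build_interactome([("XBP1", "A"), ("XBP1", "B")], seeds=["XBP1"])
        cross = cross_annotation(net, {"A", "B"}, {"A": "direct", "B": "direct"})
        assert set(cross["interaction_type"]) == {"direct"}

    def test_conflicting_types_rejected(self):
        net = build_interactome([("XBP1", "A")], seeds=["XBP1"])
        conflict = pd.DataFrame({"gene": ["A", "A"], "type": ["direct", "indirect"]})
        with pytest.raises(ValueError, match="conflicting"):
            cross_annotation(net, {"A"}, conflict)


class TestTrisetPrioritize:
    def test_disjoint_lists_empty(self):
        assert triset_prioritize({"A"}, {"B"}, {"C": "direct"}).empty

    def test_toy_single_common_gene(self):
        out = triset_prioritize({"A", "B", "C"}, {"B", "C", "D"}, {"C": "direct", "E": "direct"})
        assert list(out["gene"]) == ["C"]
        assert out.loc[0, "htt_interaction"] == "direct"

    def test_adding_gene_to_all_lists_adds_one_record(self):
        base = triset_prioritize({"A"}, {"A"}, {"A": "indirect"})
        bigger = triset_prioritize({"A", "Z"}, {"A", "Z"}, {"A": "indirect", "Z": "direct"})
        assert len(bigger) == len(base) + 1

    def test_reference_table_reconstruction(self):
        """Joining the shipped 13-gene table to its own membership lists reproduces it."""
        table = load_prioritization_table()
        genes = set(table["gene"])
        sig = ConsensusSignature(direction="up", genes=frozenset(genes))
        types = dict(zip(table["gene"], table["interaction_type"]))
        flags = table.set_index("gene")[list(MOTIF_COLUMNS)]
        corr = table[["gene", "rho", "fdr_cor"]]
        out = triset_prioritize(sig, genes, types, flags, corr)
        assert len(out) == 13
        assert (out["htt_interaction"] == "direct").sum() == 2
        assert out[list(MOTIF_COLUMNS)].any(axis=1).sum() == 8
        assert (out["fdr_cor"] < 0.01).sum() == 9
        # sorted by correlation significance
        assert (out["fdr_cor"].fillna(2).diff().dropna() >= 0).all()


def test_sif_and_edge_list_round_trip(tmp_path):
    edges, _, _ = simulate_network(n_nodes=40, n_edges=80, planted_apoptosis_overlap=4,
                                   planted_htt_overlap=1, seed=8)
    net = build_interactome(edges)
    sif = tmp_path / "net.sif"
    write_sif(net, sif)
    lines = [ln.split("\t") for ln in sif.read_text().splitlines()]
    assert sorted((a, b) for a, _, b in lines) == net.edges()
    tsv = tmp_path / "edges.tsv"
    pd.DataFrame(edges, columns=["geneA", "geneB"]).to_csv(tsv, sep="\t", index=False)
    frame = read_edge_list(tsv)
    assert build_interactome(frame).nodes == net.nodes
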