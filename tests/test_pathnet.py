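"""Pathway model, reaction coverage, collapse, cross-talk network and the
hormone shortest-path subgraph."""

import itertools

import networkx as nx
import pandas as pd
import pytest

from droughtseq.errors import DesignError
from droughtseq.pathnet import (
    PathwayDB,
    build_network,
    collapse,
    edge_weight_class,
    hormone_subnetwork,
    reaction_coverage,
    read_graphml,
    write_graphml,
    write_sif,
)


def _db(rows, hormone=(), collapse_map=None):
    table = pd.DataFrame(rows, columns=["pathway_id", "reaction_id",
                                        "gene_id"])
    table["is_hormone"] = table["pathway_id"].isin(hormone)
    return PathwayDB.from_table(table, collapse_map=collapse_map)


def _de_table(direction_by_gene):
    return pd.DataFrame(
        {"direction": pd.Series(direction_by_gene)}
    )


class TestReactionCoverage:
    def test_partial_coverage_ratio(self):
        db = _db([("P", "r1", "a"), ("P", "r2", "b"), ("P", "r3", "c")])
        out = reaction_coverage(db, {"a", "b"}, min_reactions=3)
        assert out.loc["P", "ratio"] == pytest.approx(2 / 3)

    def test_bounds(self):
        db = _db([("P", f"r{i}", g) for i, g in enumerate("abc")])
        assert reaction_coverage(db, set(), 3).loc["P", "ratio"] == 0.0
        assert reaction_coverage(db, {"a", "b", "c"}, 3).loc["P", "ratio"] == 1.0

    def test_small_pathways_excluded_by_default(self):
        db = _db([("P2", "r1", "a"), ("P2", "r2", "b"),
                  ("P3", "r3", "a"), ("P3", "r4", "b"), ("P3", "r5", "c")])
        out = reaction_coverage(db, {"a"})
        assert "P2" not in out.index and "P3" in out.index

    def test_scaffold_genes_dropped_on_load(self):
        db = _db([("P", "r1", "Sb0011s001000"), ("P", "r2", "Sb01g000100")])
        assert db.gene_universe() == {"Sb01g000100"}


class TestCollapse:
    def test_union_of_member_sets(self):
        db = _db([("P1", "r1", "a"), ("P1", "r1", "b"), ("P2", "r2", "b"),
                  ("P2", "r2", "c")])
        merged = collapse(db, {"P1": "G", "P2": "G"})
        assert merged.pathway_genes("G") == {"a", "b", "c"}

    def test_identity_map_is_noop(self):
        db = _db([("P1", "r1", "a"), ("P2", "r2", "b")])
        merged = collapse(db, {})
        assert merged.reactions == db.reactions
        assert merged.gene_universe() == db.gene_universe()

    def test_preserves_gene_universe(self, planted_experiment):
        _, _, annotations = planted_experiment
        db = annotations.pathway_db
        merged = collapse(db)
        assert merged.gene_universe() == db.gene_universe()

    def test_chained_map_resolves(self):
        db = _db([("P1", "r1", "a"), ("P2", "r2", "b")])
        merged = collapse(db, {"P1": "P2", "P2": "G"})
        assert set(merged.reactions) == {"G"}

    def test_cyclic_map_rejected(self):
        db = _db([("P1", "r1", "a"), ("P2", "r2", "b")])
        with pytest.raises(DesignError, match="cyclic"):
            collapse(db, {"P1": "P2", "P2": "P1"})

    def test_hormone_flag_inherited(self):
        db = _db([("P1", "r1", "a"), ("P2", "r2", "b")], hormone={"P1"})
        merged = collapse(db, {"P1": "G", "P2": "G"})
        assert merged.hormone == {"G"}


class TestBuildNetwork:
    def test_edge_weight_classes(self):
        assert edge_weight_class(12) == ">=10"
        assert edge_weight_class(10) == ">=10"
        assert edge_weight_class(9) == "6-9"
        assert edge_weight_class(6) == "6-9"
        assert edge_weight_class(5) == "<=5"
        assert edge_weight_class(1) == "<=5"

    def test_shared_gene_edge_and_weights(self):
        genes_ab = [f"g{i}" for i in range(12)]
        rows = [("A", "rA", g) for g in genes_ab]
        rows += [("B", "rB", g) for g in genes_ab]
        rows += [("C", "rC", "g0"), ("C", "rC2", "zz")]
        db = _db(rows)
        de = _de_table({g: "up" for g in genes_ab})
        graph = build_network(db, de)
        assert graph.edges[("A", "B")]["weight"] == 12
        assert graph.edges[("A", "B")]["weight_class"] == ">=10"
        assert graph.edges[("A", "C")]["weight"] == 1

    def test_shared_gene_counts_once_across_reactions(self):
        rows = [("A", "r1", "g"), ("A", "r2", "g"),
                ("B", "r3", "g"), ("B", "r4", "g")]
        graph = build_network(_db(rows), _de_table({"g": "up"}))
        assert graph.edges[("A", "B")]["weight"] == 1

    def test_balanced_node_is_neutral(self):
        rows = [("A", "r", g) for g in "abcdef"]
        de = _de_table({g: ("up" if g in "abc" else "down") for g in "abcdef"})
        graph = build_network(_db(rows), de)
        assert graph.nodes["A"]["score"] == 0
        assert graph.nodes["A"]["score_class"] == "neutral"

    def test_no_shared_de_genes_no_edges(self):
        rows = [("A", "r1", "a"), ("B", "r2", "b")]
        graph = build_network(_db(rows), _de_table({"a": "up", "b": "down"}))
        assert graph.number_of_edges() == 0

    def test_matches_bruteforce_intersection_oracle(self, rng):
        """Edges and weights equal pairwise set intersections computed
        naively on a random 50-pathway database."""
        genes = [f"g{i}" for i in range(300)]
        rows = []
        for p in range(50):
            for r in range(int(rng.integers(1, 4))):
                for g in rng.choice(genes, size=rng.integers(1, 8),
                                    replace=False):
                    rows.append((f"P{p}", f"P{p}r{r}", g))
        db = _db(rows)
        de_genes = set(rng.choice(genes, size=120, replace=False).tolist())
        directions = {
            g: ("up" if rng.random() < 0.5 else "down") for g in de_genes
        }
        graph = build_network(db, _de_table(directions))
        # brute force
        de_by_pwy = {
            p: db.pathway_genes(p) & de_genes
            for p in db.pathways()
            if db.pathway_genes(p) & de_genes
        }
        expected_edges = {}
        for a, b in itertools.combinations(sorted(de_by_pwy), 2):
            shared = de_by_pwy[a] & de_by_pwy[b]
            if shared:
                expected_edges[(a, b)] = len(shared)
        assert {tuple(sorted(e)) for e in graph.edges} == set(expected_edges)
        for (a, b), w in expected_edges.items():
            assert graph.edges[(a, b)]["weight"] == w
        for p, genes_p in de_by_pwy.items():
            n_up = sum(1 for g in genes_p if directions[g] == "up")
            assert graph.nodes[p]["score"] == n_up - (len(genes_p) - n_up)


class TestHormoneSubnetwork:
    @staticmethod
    def _toy_graph(edges, hormones):
        graph = nx.Graph()
        graph.add_edges_from(edges)
        for n in graph.nodes:
            graph.nodes[n]["is_hormone"] = n in hormones
        return graph

    def test_direct_edge_only(self):
        graph = self._toy_graph([("A", "I"), ("A", "x"), ("x", "y")],
                                {"A", "I"})
        sub = hormone_subnetwork(graph, {"A", "I"})
        assert set(sub.nodes) == {"A", "I"}

    def test_tied_shortest_paths_both_included(self):
        graph = self._toy_graph(
            [("A", "x"), ("x", "B"), ("A", "y"), ("y", "B"), ("A", "z"),
             ("z", "w"), ("w", "B")],
            {"A", "B"},
        )
        sub = hormone_subnetwork(graph, {"A", "B"})
        assert set(sub.nodes) == {"A", "B", "x", "y"}  # z-w path is longer

    def test_disconnected_hormones_kept_as_isolates(self):
        graph = self._toy_graph([("A", "x"), ("B", "y")], {"A", "B"})
        sub = hormone_subnetwork(graph, {"A", "B"})
        assert {"A", "B"} <= set(sub.nodes)
        assert sub.degree("B") <= 1

    def test_matches_exhaustive_path_enumeration(self, rng):
        """Shortest-path node set equals brute-force enumeration of all
        simple paths on 10-node toys."""
        for _ in range(10):
            graph = nx.gnp_random_graph(10, 0.3,
                                        seed=int(rng.integers(1 << 30)))
            graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in range(10)})
            hormones = {"n0", "n1", "n2"}
            for n in graph.nodes:
                graph.nodes[n]["is_hormone"] = n in hormones
            sub = hormone_subnetwork(graph, hormones)
            expected = set(hormones) & set(graph.nodes)
            for a, b in itertools.combinations(sorted(hormones), 2):
                if a in graph and b in graph and nx.has_path(graph, a, b):
                    dist = nx.shortest_path_length(graph, a, b)
                    for path in nx.all_simple_paths(graph, a, b,
                                                    cutoff=dist):
                        if len(path) - 1 == dist:
                            expected.update(path)
            assert set(sub.nodes) == expected

    def test_neighbor_mode(self):
        graph = self._toy_graph([("A", "x"), ("x", "y"), ("y", "B")],
                                {"A", "B"})
        sub = hormone_subnetwork(graph, {"A", "B"}, mode="neighbors")
        assert set(sub.nodes) == {"A", "B", "x", "y"}

    def test_needs_two_hormones(self):
        graph = self._toy_graph([("A", "x")], {"A"})
        with pytest.raises(DesignError):
            hormone_subnetwork(graph, {"A"})


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        rows = [("A", "r1", g) for g in "abcdefg"]
        rows += [("B", "r2", g) for g in "abc"]
        graph = build_network(
            _db(rows), _de_table({g: "up" for g in "abcdefg"})
        )
        path = tmp_path / "net.graphml"
        write_graphml(graph, path)
        loaded = read_graphml(path)
        assert set(loaded.nodes) == set(graph.nodes)
        assert set(map(tuple, map(sorted, loaded.edges))) == set(
            map(tuple, map(sorted, graph.edges))
        )
        assert loaded.edges[("A", "B")]["weight"] == 3
        assert loaded.nodes["A"]["score"] == 7

    def test_sif_export(self, tmp_path):
        rows = [("A", "r1", "a"), ("B", "r2", "a"), ("C", "r3", "zz")]
        db = _db(rows)
        graph = build_network(db, _de_table({"a": "down", "zz": "up"}))
        sif = tmp_path / "net.sif"
        write_sif(graph, sif, node_attr_path=tmp_path / "nodes.tsv",
                  edge_attr_path=tmp_path / "edges.tsv")
        lines = sif.read_text().strip().splitlines()
        assert "A\tshares_de_genes\tB" in lines
        assert "C" in lines  # isolated node retained
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        assert set(nodes["node"]) == {"A", "B", "C"}
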