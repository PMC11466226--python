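"""Encoders, decoders and their structural invariants."""

import pandas as pd
import pytest

import hiertax as hx
from conftest import brute_force_closure

from hiertax.encodings import ADJACENCY, CLOSURE, MATERIALIZED_PATH, NESTED_SET


def chain_taxonomy():
    return hx.build_taxonomy(["A", "B", "C"], [("A", "B"), ("B", "C")])


def singleton():
    return hx.build_taxonomy([hx.TaxonNode("X")], [])


class TestAdjacency:
    def test_fig1_rows(self, fig1):
        df = hx.encode_adjacency(fig1).table("nodes")
        rows = set(zip(df["node_id"], df["parent_id"]))
        assert rows == {("A", ""), ("B", "A"), ("C", "A"), ("D", "C")}

    def test_singleton(self):
        df = hx.encode_adjacency(singleton()).table("nodes")
        assert df[["node_id", "parent_id"]].values.tolist() == [["X", ""]]

    def test_star_shares_one_parent(self):
        t = hx.build_taxonomy(
            ["hub", "a", "b", "c"], [("hub", "a"), ("hub", "b"), ("hub", "c")]
        )
        df = hx.encode_adjacency(t).table("nodes")
        assert len(df) == 4
        assert (df["parent_id"] == "hub").sum() == 3


class TestMaterializedPath:
    def test_fig1_paths(self, fig1):
        df = hx.encode_materialized_path(fig1, "|").table("nodes")
        paths = dict(zip(df["node_id"], df["path"]))
        assert paths == {"A": "", "B": "A", "C": "A", "D": "A|C"}

    def test_delimiter_in_id_rejected(self):
        t = hx.build_taxonomy(["A|1", "B"], [("A|1", "B")])
        with pytest.raises(hx.DelimiterError):
            hx.encode_materialized_path(t, "|")

    @pytest.mark.parametrize("seed", range(8))
    def test_child_path_extends_parent_path(self, random_taxonomy, seed):
        t = random_taxonomy(seed)
        b = hx.encode_materialized_path(t)
        paths = dict(zip(b.table("nodes")["node_id"], b.table("nodes")["path"]))
        for parent, child in t.edges():
            expected = f"{paths[parent]}{b.delimiter}{parent}" if paths[parent] else parent
            assert paths[child] == expected
        for root in t.roots:
            assert paths[root] == ""


class TestNestedSet:
    def test_fig1_numbering(self, fig1):
        df = hx.encode_nested_set(fig1).table("nodes").set_index("node_id")
        got = {n: (r["lft"], r["rgt"], r["depth"]) for n, r in df.iterrows()}
        assert got == {
            "A": (1, 8, 0),
            "B": (2, 3, 1),
            "C": (4, 7, 1),
            "D": (5, 6, 2),
        }

    def test_chain_numbering(self):
        df = hx.encode_nested_set(chain_taxonomy()).table("nodes").set_index("node_id")
        assert (df.loc["A", "lft"], df.loc["A", "rgt"]) == (1, 6)
        assert (df.loc["B", "lft"], df.loc["B", "rgt"]) == (2, 5)
        assert (df.loc["C", "lft"], df.loc["C", "rgt"]) == (3, 4)

    def test_singleton(self):
        df = hx.encode_nested_set(singleton()).table("nodes")
        assert df[["lft", "rgt", "depth"]].values.tolist() == [[1, 2, 0]]

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_and_leaf_predicate(self, random_taxonomy, seed):
        t = random_taxonomy(seed, n_nodes=10 + seed * 13)
        df = hx.encode_nested_set(t).table("nodes")
        n = len(df)
        assert sorted(df["lft"].tolist() + df["rgt"].tolist()) == list(
            range(1, 2 * n + 1)
        )
        leaves = set(t.leaves)
        for _, row in df.iterrows():
            assert (row["lft"] == row["rgt"] - 1) == (row["node_id"] in leaves)
            assert row["depth"] == t.depth(row["node_id"])

    def test_forest_components_numbered_consecutively(self):
        t = hx.build_taxonomy(
            [hx.TaxonNode("R1", sort_key=0), hx.TaxonNode("R2", sort_key=1), "c1"],
            [("R1", "c1")],
        )
        df = hx.encode_nested_set(t).table("nodes").set_index("node_id")
        assert (df.loc["R1", "lft"], df.loc["R1", "rgt"]) == (1, 4)
        assert (df.loc["R2", "lft"], df.loc["R2", "rgt"]) == (5, 6)


class TestClosure:
    def test_fig1_rows(self, fig1):
        bundle = hx.encode_closure(fig1)
        assert bundle.table_count == 2
        hier = bundle.table("hierarchy")
        assert len(hier) == 8
        pairs = set(zip(hier["ancestor_id"], hier["descendant_id"], hier["depth"]))
        selfrows = {(n, n, 0) for n in "ABCD"}
        assert pairs == selfrows | {("A", "B", 1), ("A", "C", 1), ("C", "D", 1), ("A", "D", 2)}

    def test_singleton_single_self_row(self):
        hier = hx.encode_closure(singleton()).table("hierarchy")
        assert hier.values.tolist() == [["X", "X", 0]]

    def test_hybrid_dag_min_depth(self, fig1):
        dag = hx.build_dag(fig1.nodes, list(fig1.edges()) + [("B", "D")])
        hier = hx.encode_closure(dag).table("hierarchy")
        pairs = {
            (a, d): k
            for a, d, k in zip(hier["ancestor_id"], hier["descendant_id"], hier["depth"])
        }
        assert pairs[("B", "D")] == 1
        assert pairs[("A", "D")] == 2  # min over A-C-D and A-B-D

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, random_taxonomy, seed):
        t = random_taxonomy(seed, n_nodes=15 + seed * 11)
        hier = hx.encode_closure(t).table("hierarchy")
        got = set(zip(hier["ancestor_id"], hier["descendant_id"], hier["depth"]))
        assert got == brute_force_closure(t)
        assert len(hier) == sum(t.depth(n) + 1 for n in t.node_ids)

    def test_uniparental_dag_equals_taxonomy_closure(self, random_taxonomy):
        t = random_taxonomy(11)
        dag = hx.build_dag(t.nodes, t.edges())
        a = hx.encode_closure(t).table("hierarchy")
        b = hx.encode_closure(dag).table("hierarchy")
        key = lambda df: set(zip(df["ancestor_id"], df["descendant_id"], df["depth"]))
        assert key(a) == key(b)


class TestBundleShape:
    @pytest.mark.parametrize(
        "model, n_tables",
        [(ADJACENCY, 1), (MATERIALIZED_PATH, 1), (NESTED_SET, 1), (CLOSURE, 2)],
    )
    def test_table_counts(self, fig1, model, n_tables):
        assert hx.encode(fig1, model).table_count == n_tables


class TestDecode:
    @pytest.mark.parametrize("model", hx.MODELS)
    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_identity(self, random_taxonomy, model, seed, fig1):
        for t in (fig1, random_taxonomy(seed, n_nodes=5 + seed * 23)):
            assert hx.decode(hx.encode(t, model)) == t

    def test_nested_set_preserves_sibling_order(self, fig1):
        back = hx.decode(hx.encode_nested_set(fig1))
        assert back.children_of("A") == ["B", "C"]

    def test_overlapping_intervals_rejected(self):
        df = pd.DataFrame(
            {"node_id": ["A", "B", "C"], "lft": [1, 2, 3], "rgt": [4, 5, 6], "depth": [0, 1, 1]}
        )
        with pytest.raises(hx.ConsistencyError):
            hx.decode(hx.ModelTableBundle(NESTED_SET, {"nodes": df}))

    def test_non_permutation_rejected(self):
        df = pd.DataFrame(
            {"node_id": ["A", "B"], "lft": [1, 3], "rgt": [6, 4], "depth": [0, 1]}
        )
        with pytest.raises(hx.ConsistencyError):
            hx.decode(hx.ModelTableBundle(NESTED_SET, {"nodes": df}))

    def test_closure_missing_transitive_row_rejected(self):
        hier = pd.DataFrame(
            {
                "ancestor_id": ["A", "C", "A", "C", "D"],
                "descendant_id": ["A", "C", "C", "D", "D"],
                "depth": [0, 0, 1, 1, 0],
            }
        )  # lacks (A, D, 2)
        nodes = pd.DataFrame(
            {"node_id": ["A", "C", "D"], "name": [None] * 3, "rank": [None] * 3}
        )
        with pytest.raises(hx.ConsistencyError):
            hx.decode(hx.ModelTableBundle(CLOSURE, {"nodes": nodes, "hierarchy": hier}))

    def test_closure_missing_self_rows_rejected(self):
        hier = pd.DataFrame(
            {"ancestor_id": ["A"], "descendant_id": ["B"], "depth": [1]}
        )
        nodes = pd.DataFrame(
            {"node_id": ["A", "B"], "name": [None] * 2, "rank": [None] * 2}
        )
        with pytest.raises(hx.ConsistencyError):
            hx.decode(hx.ModelTableBundle(CLOSURE, {"nodes": nodes, "hierarchy": hier}))

    def test_orphan_path_prefix_rejected(self):
        df = pd.DataFrame({"node_id": ["A", "D"], "path": ["", "A|C"]})
        with pytest.raises(hx.ConsistencyError):
            hx.decode(hx.ModelTableBundle(MATERIALIZED_PATH, {"nodes": df}))

    def test_adjacency_cycle_rejected(self):
        df = pd.DataFrame({"node_id": ["A", "B"], "parent_id": ["B", "A"]})
        with pytest.raises(hx.ConsistencyError):
            hx.decode(hx.ModelTableBundle(ADJACENCY, {"nodes": df}))

    def test_multiparental_closure_decodes_to_dag(self, fig1):
        dag = hx.build_dag(fig1.nodes, list(fig1.edges()) + [("B", "D")])
        back = hx.decode(hx.encode_closure(dag))
        assert isinstance(back, hx.TaxonDag)
        assert back == dag
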