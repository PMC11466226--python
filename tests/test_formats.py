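"""Serialization round trips: model CSVs, Darwin Core, rank columns, Newick."""

import pandas as pd
import pytest

import hiertax as hx
from hiertax import formats


class TestModelCsv:
    @pytest.mark.parametrize("model", hx.MODELS)
    def test_write_read_identity_fig1(self, fig1, model, tmp_path):
        paths = hx.write_model_csv(hx.encode(fig1, model), tmp_path)
        assert hx.decode(hx.read_model_csv(paths, model)) == fig1

    @pytest.mark.parametrize("model", hx.MODELS)
    @pytest.mark.parametrize("seed", [1, 17])
    def test_write_read_identity_random(self, random_taxonomy, model, seed, tmp_path):
        t = random_taxonomy(seed, n_nodes=35)
        paths = hx.write_model_csv(hx.encode(t, model), tmp_path)
        assert hx.decode(hx.read_model_csv(paths, model)) == t

    def test_column_order_is_stable(self, fig1, tmp_path):
        (path,) = hx.write_model_csv(hx.encode_nested_set(fig1), tmp_path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("node_id,lft,rgt,depth")

    def test_parent_id_alias_accepted_in_closure_hierarchy(self, fig1, tmp_path):
        nodes_p, hier_p = sorted(
            hx.write_model_csv(hx.encode_closure(fig1), tmp_path),
            key=lambda p: p.name,
        )
        df = pd.read_csv(hier_p)
        df.rename(columns={"ancestor_id": "parent_id"}).to_csv(hier_p, index=False)
        bundle = hx.read_model_csv([nodes_p, hier_p], "closure_table")
        assert hx.decode(bundle) == fig1

    def test_missing_column_raises(self, fig1, tmp_path):
        (path,) = hx.write_model_csv(hx.encode_nested_set(fig1), tmp_path)
        df = pd.read_csv(path).drop(columns=["rgt"])
        df.to_csv(path, index=False)
        with pytest.raises(hx.HeaderError):
            hx.read_model_csv(path, "nested_set")

    def test_tsv_by_extension(self, fig1, tmp_path):
        df = hx.encode_adjacency(fig1).table("nodes")
        out = tmp_path / "adjacency_list.tsv"
        df.to_csv(out, sep="\t", index=False)
        assert hx.decode(hx.read_model_csv(out, "adjacency_list")) == fig1


class TestDarwinCore:
    def test_fig1_paths(self, fig1):
        df = hx.write_dwc(fig1).set_index("node_id")
        assert df.loc["D", "higherClassification"] == "A | C"
        assert df.loc["A", "higherClassification"] == ""

    def test_round_trip_when_names_unique(self, random_taxonomy):
        t = random_taxonomy(21)
        back = hx.read_dwc(hx.write_dwc(t))
        assert back.topology_equal(t)
        assert all(back.node(n).name == t.node(n).name for n in t.node_ids)

    def test_duplicate_sibling_names_ambiguous(self):
        df = pd.DataFrame(
            {
                "scientificName": ["Rosa", "canina", "canina"],
                "higherClassification": ["", "Rosa", "Rosa"],
            }
        )
        with pytest.raises(hx.AmbiguousNameError):
            hx.read_dwc(df)

    def test_orphan_prefix_rejected(self):
        df = pd.DataFrame(
            {
                "scientificName": ["Rosa", "canina"],
                "higherClassification": ["", "Plantae | Rosa"],
            }
        )
        with pytest.raises(hx.OrphanPathError):
            hx.read_dwc(df)

    def test_reimport_equals_name_path_encoding(self, random_taxonomy):
        """DwC re-imported then path-encoded over names equals encoding the
        original tree's name paths directly."""
        t = random_taxonomy(33)
        back = hx.read_dwc(hx.write_dwc(t))
        paths_back = {
            back.node(n).name: [back.node(a).name for a in back.ancestors(n)]
            for n in back.node_ids
        }
        paths_direct = {
            t.node(n).name: [t.node(a).name for a in t.ancestors(n)]
            for n in t.node_ids
        }
        assert paths_back == paths_direct


class TestRankColumns:
    def test_ancestor_names_land_in_rank_cells(self):
        nodes = [
            hx.TaxonNode("f1", name="Rosaceae", rank="family"),
            hx.TaxonNode("g1", name="Rosa", rank="genus"),
            hx.TaxonNode("s1", name="Rosa canina", rank="species"),
        ]
        t = hx.build_taxonomy(nodes, [("f1", "g1"), ("g1", "s1")])
        df = hx.write_rank_columns(t, ["family", "genus", "species"]).set_index("node_id")
        assert df.loc["s1", "family"] == "Rosaceae"
        assert df.loc["s1", "genus"] == "Rosa"
        assert df.loc["g1", "species"] == ""

    def test_unranked_ancestors_skipped_with_count(self):
        t = hx.build_taxonomy(
            [hx.TaxonNode("a"), hx.TaxonNode("b")], [("a", "b")]
        )
        df = hx.write_rank_columns(t, ["genus"])
        assert (df["genus"] == "").all()
        assert df.attrs["unranked_skipped"] > 0

    def test_duplicate_rank_on_path_rejected(self):
        nodes = [
            hx.TaxonNode("g1", name="X", rank="genus"),
            hx.TaxonNode("g2", name="Y", rank="genus"),
        ]
        t = hx.build_taxonomy(nodes, [("g1", "g2")])
        with pytest.raises(hx.DuplicateRankOnPathError):
            hx.write_rank_columns(t, ["genus"])


class TestDualExport:
    def test_fig1_counts(self, fig1):
        checklist, closure = hx.write_dual_export(fig1)
        assert len(checklist) == 4
        assert len(closure.table("hierarchy")) == 8

    def test_id_sets_shared(self, random_taxonomy):
        t = random_taxonomy(5)
        checklist, closure = hx.write_dual_export(t)
        assert set(checklist["node_id"]) == set(closure.table("nodes")["node_id"])

    def test_formal_part_detected_as_closure(self, random_taxonomy):
        t = random_taxonomy(6)
        _, closure = hx.write_dual_export(t)
        assert hx.detect_model(list(closure.tables.values())).verdict == "closure_table"


class TestNewick:
    def test_fig1_string(self, fig1):
        assert hx.write_newick(fig1) == "(B,(D)C)A;"

    def test_singleton(self):
        t = hx.build_taxonomy(["X"], [])
        assert hx.write_newick(t) == "X;"

    @pytest.mark.parametrize("seed", [3, 19, 42])
    def test_round_trip_preserves_topology_and_order(self, random_taxonomy, seed):
        t = random_taxonomy(seed)
        back = hx.read_newick(hx.write_newick(t))
        assert back.topology_equal(t, ordered=True)

    def test_forest_rejected(self):
        t = hx.build_taxonomy(["P", "Q"], [])
        with pytest.raises(hx.MultirootError):
            hx.write_newick(t)

    def test_malformed_string_rejected(self):
        with pytest.raises(hx.ParseError):
            hx.read_newick("((A,B;")

    def test_labels_needing_quotes(self):
        t = hx.build_taxonomy(["Rosa canina", "r"], [("r", "Rosa canina")])
        text = hx.write_newick(t)
        assert "'Rosa canina'" in text
        assert hx.read_newick(text).topology_equal(t, ordered=True)
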