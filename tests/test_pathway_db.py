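"""Pathway parsing, validation and collection indexing."""

import pytest
from hypothesis import given, strategies as st

from ipfenrich import (
    Pathway,
    PathwayNode,
    build_collection,
    load_collection,
    parse_kgml,
    parse_pathway_tsv,
    write_collection,
    write_pathway_tsv,
)

from conftest import chain_pathway, make_pathway

KGML_ONE_GENE = """<?xml version="1.0"?>
<pathway name="path:syn00001" title="one box">
  <entry id="1" name="hsa:2475" type="gene"/>
</pathway>
"""

KGML_TWO_GENES_RELATED = """<?xml version="1.0"?>
<pathway name="path:syn00002" title="two boxes">
  <entry id="1" name="hsa:2475" type="gene"/>
  <entry id="2" name="hsa:207 hsa:208" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel"/>
</pathway>
"""

KGML_GROUP = """<?xml version="1.0"?>
<pathway name="path:syn00003" title="complex box">
  <entry id="1" name="hsa:2475" type="gene"/>
  <entry id="2" name="hsa:6198" type="gene"/>
  <entry id="3" type="group">
    <component id="1"/>
    <component id="2"/>
  </entry>
  <entry id="4" name="hsa:207" type="gene"/>
  <relation entry1="1" entry2="4" type="PPrel"/>
</pathway>
"""


class TestKgml:
    def test_single_gene_entry(self, tmp_path):
        f = tmp_path / "p.xml"
        f.write_text(KGML_ONE_GENE)
        p = parse_kgml(f)
        assert p.pathway_id == "syn00001"
        assert len(p.nodes) == 1
        assert p.nodes[0].kind == "single"
        assert p.nodes[0].genes == {"hsa:2475"}
        assert not p.edges

    def test_relation_becomes_undirected_edge(self, tmp_path):
        f = tmp_path / "p.xml"
        f.write_text(KGML_TWO_GENES_RELATED)
        p = parse_kgml(f)
        assert len(p.nodes) == 2
        kinds = {n.node_id: n.kind for n in p.nodes}
        assert kinds == {"1": "single", "2": "homolog_group"}
        assert p.edges == {("1", "2")}

    def test_group_absorbs_components(self, tmp_path):
        # hand count of the fixture: 4 entries, one group of 2 components;
        # expected boxes = group + the standalone gene = 2
        f = tmp_path / "p.xml"
        f.write_text(KGML_GROUP)
        p = parse_kgml(f)
        assert len(p.nodes) == 2
        by_id = {n.node_id: n for n in p.nodes}
        assert by_id["3"].kind == "complex"
        assert by_id["3"].genes == {"hsa:2475", "hsa:6198"}
        assert "1" not in by_id and "2" not in by_id
        # relation to an absorbed component re-attaches to the group
        assert p.edges == {("3", "4")}

    def test_malformed_xml_names_line(self, tmp_path):
        f = tmp_path / "p.xml"
        f.write_text("<pathway><entry id='1'\n</pathway>")
        with pytest.raises(ValueError, match="line"):
            parse_kgml(f)

    def test_gene_entry_without_names_rejected(self, tmp_path):
        f = tmp_path / "p.xml"
        f.write_text('<pathway name="x"><entry id="1" type="gene" name=""/></pathway>')
        with pytest.raises(ValueError, match="no gene names"):
            parse_kgml(f)

    def test_relation_to_unknown_entry_rejected(self, tmp_path):
        f = tmp_path / "p.xml"
        f.write_text(
            '<pathway name="x"><entry id="1" name="hsa:1" type="gene"/>'
            '<relation entry1="1" entry2="99"/></pathway>'
        )
        with pytest.raises(ValueError, match="unknown entry"):
            parse_kgml(f)

    def test_self_relation_dropped_with_warning(self, tmp_path):
        f = tmp_path / "p.xml"
        f.write_text(
            '<pathway name="x"><entry id="1" name="hsa:1" type="gene"/>'
            '<relation entry1="1" entry2="1"/></pathway>'
        )
        with pytest.warns(UserWarning, match="self-relation"):
            p = parse_kgml(f)
        assert not p.edges


class TestTsvDialect:
    def test_path_graph_round(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text(
            "pathway\tpw1\ttest\n"
            "node\tn1\tsingle\tA\n"
            "node\tn2\tsingle\tB\n"
            "node\tn3\tsingle\tC\n"
            "edge\tn1\tn2\n"
            "edge\tn2\tn3\n"
        )
        p = parse_pathway_tsv(f)
        assert p.pathway_id == "pw1" and p.name == "test"
        assert len(p.nodes) == 3
        assert p.edges == {("n1", "n2"), ("n2", "n3")}

    def test_single_with_two_genes_rejected(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("pathway\tpw1\nnode\tn1\tsingle\tA,B\n")
        with pytest.raises(ValueError, match="single"):
            parse_pathway_tsv(f)

    def test_unknown_kind_rejected_with_line(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("pathway\tpw1\nnode\tn1\tmega\tA\n")
        with pytest.raises(ValueError, match=":2"):
            parse_pathway_tsv(f)

    def test_duplicate_node_id_rejected(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("node\tn1\tsingle\tA\nnode\tn1\tsingle\tB\n")
        with pytest.raises(ValueError, match="duplicate node id"):
            parse_pathway_tsv(f)

    def test_edgeless_pathway_accepted(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("pathway\tpw1\nnode\tn1\tsingle\tA\n")
        p = parse_pathway_tsv(f)
        assert p.edges == frozenset()

    @given(
        genes=st.lists(
            st.sampled_from("ABCDEFGH"), min_size=1, max_size=8, unique=True
        )
    )
    def test_round_trip_preserves_structure(self, genes):
        import tempfile
        from pathlib import Path

        p = chain_pathway("pwX", genes)
        with tempfile.TemporaryDirectory() as d:
            f = Path(d) / "p.tsv"
            write_pathway_tsv(p, f)
            q = parse_pathway_tsv(f)
        assert q.pathway_id == p.pathway_id
        assert [(n.node_id, n.kind, n.genes) for n in q.nodes] == [
            (n.node_id, n.kind, n.genes) for n in p.nodes
        ]
        assert q.edges == p.edges


class TestValidation:
    def test_node_needs_genes(self):
        with pytest.raises(ValueError):
            PathwayNode("n1", "complex", [])

    def test_edge_endpoints_must_exist(self):
        with pytest.raises(ValueError, match="unknown node"):
            make_pathway("p", [("n1", "single", ["A"])], [("n1", "nX")])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            make_pathway("p", [("n1", "single", ["A"])], [("n1", "n1")])

    def test_duplicate_edges_collapse(self):
        p = make_pathway(
            "p",
            [("n1", "single", ["A"]), ("n2", "single", ["B"])],
            [("n1", "n2"), ("n2", "n1")],
        )
        assert p.edges == {("n1", "n2")}


class TestCollection:
    def test_single_pathway_index(self):
        p = chain_pathway("pw1", ["A"])
        coll = build_collection([p])
        assert coll.M == 1
        assert coll.gene_index["A"] == {"pw1"}

    def test_shared_gene_counted_in_both(self, toy_collection):
        assert toy_collection.gene_index["TP53"] == {"pwA", "pwB"}
        assert toy_collection.df("TP53") == 2

    def test_absent_gene_not_indexed(self, toy_collection):
        assert "NOPE" not in toy_collection.gene_index
        assert toy_collection.df("NOPE") == 0

    def test_duplicate_pathway_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate pathway ids"):
            build_collection([chain_pathway("pw1", ["A"]), chain_pathway("pw1", ["B"])])

    def test_index_is_membership_transpose(self, toy_collection):
        lhs = sum(len(v) for v in toy_collection.gene_index.values())
        rhs = sum(len(p.gene_set) for p in toy_collection.pathways)
        assert lhs == rhs

    def test_collection_write_load_round_trip(self, toy_collection, tmp_path):
        write_collection(toy_collection, tmp_path / "coll")
        loaded = load_collection(tmp_path / "coll")
        assert loaded.M == toy_collection.M
        assert loaded.gene_index == toy_collection.gene_index
        for p in toy_collection.pathways:
            assert loaded[p.pathway_id].edges == p.edges
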