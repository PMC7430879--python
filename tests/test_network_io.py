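"""Loading, deduplication, validation and canonicalization of curated tables."""

import io
import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from immunet import (
    EdgeRecord,
    NodeRecord,
    OntologyMap,
    canonicalize_names,
    deduplicate_edges,
    load_network_tables,
    validate_network,
    write_edge_table,
    write_node_table,
)
from immunet.network_io import load_edge_table, load_node_table
from immunet.records import SchemaError, VocabularyError

from conftest import make_edge, make_nodes


def csv(text: str) -> io.StringIO:
    return io.StringIO(textwrap.dedent(text).strip() + "\n")


EDGE_CSV = """\
    Source Node,Target Node,Edge Effect,Reference,Receptor,Curator Initials
    macrophage,IL6,secrete,"p. 90, Fig 3-10",,MA
    IL6,Th17 cell,polarize,p. 102,IL6R,MA
    dendritic cell,naive CD4 T cell,activate,p. 350,TCR,VT
"""

NODE_CSV = """\
    Name,Type,Subtype,Species Specificity
    macrophage,Cell,myeloid,both
    IL6,Cytokine,interleukin,
    Th17 cell,Cell,lymphocyte,
    dendritic cell,Cell,myeloid,
    naive CD4 T cell,Cell,lymphocyte,
"""


class TestLoading:
    def test_rows_become_records_in_order_with_aliases_and_extras(self):
        edges, nodes = load_network_tables(csv(EDGE_CSV), csv(NODE_CSV))
        assert [e.source_node for e in edges] == ["macrophage", "IL6",
                                                  "dendritic cell"]
        assert edges[0].edge_effect == "secrete"
        assert edges[0].reference == "p. 90, Fig 3-10"
        assert edges[1].receptor == "IL6R"
        assert edges[0].receptor is None
        # unknown column survives in extras
        assert edges[0].extras["Curator Initials"] == "MA"
        assert [n.name for n in nodes][:2] == ["macrophage", "IL6"]
        assert nodes[0].node_type == "cell"  # case-normalized
        assert nodes[0].species_specificity == "both"

    def test_header_only_and_empty_files_yield_empty_lists(self):
        edges = load_edge_table(csv("source,target,effect,reference"))
        assert edges == []
        assert load_edge_table(io.StringIO("")) == []
        assert load_node_table(io.StringIO("")) == []

    def test_missing_required_column_names_the_column(self):
        with pytest.raises(SchemaError, match="edge_effect"):
            load_edge_table(csv("source,target,reference\nA,B,p. 1"))
        with pytest.raises(SchemaError, match="subtype"):
            load_node_table(csv("name,type\nA,cell"))

    def test_unknown_edge_effect_reports_row_index(self):
        bad = csv("""\
            source,target,effect,reference
            A,B,activate,p. 1
            B,C,activate,p. 2
            C,D,obliterate,p. 3
        """)
        with pytest.raises(VocabularyError, match="row 2.*obliterate"):
            load_edge_table(bad)

    def test_unknown_node_type_reports_row_index(self):
        with pytest.raises(VocabularyError, match="row 1"):
            load_node_table(csv("name,type,subtype\nA,cell,x\nB,gene,y"))

    def test_round_trip_preserves_fields(self, tmp_path):
        edges, nodes = load_network_tables(csv(EDGE_CSV), csv(NODE_CSV))
        ep, np_ = tmp_path / "e.csv", tmp_path / "n.csv"
        write_edge_table(edges, ep)
        write_node_table(nodes, np_)
        edges2, nodes2 = load_network_tables(ep, np_)
        assert edges2 == edges
        assert nodes2 == nodes


class TestDeduplication:
    def test_duplicate_triple_merges_references_keeps_first_position(self):
        records = [
            make_edge("A", "B", "activate", reference="p. 1"),
            make_edge("B", "C", "inhibit", reference="p. 2"),
            make_edge("A", "B", "activate", reference="p. 9", receptor="TLR4"),
        ]
        out = deduplicate_edges(records)
        assert [r.key for r in out] == [("A", "B", "activate"),
                                        ("B", "C", "inhibit")]
        assert out[0].reference == "p. 1; p. 9"
        assert out[0].receptor == "TLR4"  # union of optional annotations

    def test_count_matches_brute_force_distinct_triples(self):
        import numpy as np
        rng = np.random.default_rng(42)
        records = [
            make_edge(f"N{rng.integers(5)}", f"N{rng.integers(5)}",
                      ("activate", "inhibit", "secrete")[rng.integers(3)],
                      reference=f"p. {i}")
            for i in range(50)
        ]
        expected = len({r.key for r in records})  # oracle: exhaustive scan
        assert len(deduplicate_edges(records)) == expected

    @given(st.lists(st.tuples(st.sampled_from("ABCD"), st.sampled_from("ABCD"),
                              st.sampled_from(["activate", "inhibit"])),
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_never_grows(self, triples):
        records = [make_edge(s, t, e, reference=f"p. {i}")
                   for i, (s, t, e) in enumerate(triples)]
        once = deduplicate_edges(records)
        assert len(once) <= len(records)
        assert deduplicate_edges(once) == once
        if len({r.key for r in records}) == len(records):
            assert len(once) == len(records)


class TestValidation:
    def test_secretion_of_a_cell_is_an_r2_error(self):
        nodes = make_nodes(["Macrophage", "T cell"])
        edges = [make_edge("Macrophage", "T cell", "secrete")]
        report = validate_network(edges, nodes)
        assert any(f.rule == "R2" for f in report.errors)
        assert not report.passed

    def test_secrete_from_non_cell_source_is_an_r2_error(self):
        nodes = make_nodes(["IL6"], "cytokine") + make_nodes(["X"], "antigen")
        edges = [make_edge("IL6", "X", "secrete")]
        report = validate_network(edges, nodes)
        assert sum(f.rule == "R2" for f in report.errors) == 1

    def test_empty_tables_pass_vacuously(self):
        report = validate_network([], [])
        assert report.passed and report.findings == []

    def test_unknown_endpoint_is_exactly_one_r1_error(self):
        nodes = make_nodes(["A", "B"])
        edges = [make_edge("A", "B"), make_edge("A", "GHOST")]
        report = validate_network(edges, nodes)
        r1 = [f for f in report.errors if f.rule == "R1"]
        # oracle: set difference of endpoint names vs node names
        assert len(r1) == 1 and "GHOST" in r1[0].message

    def test_duplicate_nodes_isolated_nodes_and_self_loops(self):
        nodes = make_nodes(["A", "B", "A", "lonely"])
        edges = [make_edge("A", "B"), make_edge("B", "B")]
        report = validate_network(edges, nodes)
        assert any(f.rule == "R3" for f in report.errors)
        assert any(f.rule == "R4" and "lonely" in f.message
                   for f in report.warnings)
        assert any(f.rule == "R5" for f in report.warnings)  # warning only

    def test_rules_are_extensible_and_removable(self):
        nodes = make_nodes(["A"])
        custom = lambda edges, nodes, types: []
        report = validate_network([], nodes, rules={"R4": None, "R9": custom})
        assert report.passed and report.findings == []


class TestCanonicalization:
    def test_single_substitution(self):
        om = OntologyMap({"node": {"Mφ": "Macrophage"}})
        edges = [make_edge("Mφ", "IL6", "secrete")]
        nodes = [NodeRecord("Mφ", "cell"), NodeRecord("IL6", "cytokine")]
        new_edges, new_nodes, unmapped = canonicalize_names(edges, nodes, om)
        assert new_edges[0].source_node == "Macrophage"
        assert new_nodes[0].name == "Macrophage"
        assert unmapped == ["IL6"]

    def test_empty_ontology_is_identity(self):
        edges = [make_edge("A", "B")]
        nodes = make_nodes(["A", "B"])
        new_edges, new_nodes, _ = canonicalize_names(edges, nodes, OntologyMap())
        assert new_edges == edges and new_nodes == nodes

    def test_alias_collapse_count_matches_hand_oracle(self):
        # 10 aliases over 4 canonical names, applied exhaustively by hand
        aliases = {f"a{i}": f"C{i % 4}" for i in range(10)}
        om = OntologyMap({"node": aliases})
        edges = [make_edge(f"a{i}", f"a{(i + 1) % 10}") for i in range(10)]
        nodes = make_nodes([f"a{i}" for i in range(10)])
        new_edges, new_nodes, _ = canonicalize_names(edges, nodes, om)
        seen = {e.source_node for e in new_edges} | {e.target_node for e in new_edges}
        assert seen == {"C0", "C1", "C2", "C3"}

    def test_conflicting_mapping_is_a_configuration_error(self):
        om = OntologyMap()
        om.add("Mφ", "Macrophage")
        with pytest.raises(ValueError, match="conflicting"):
            om.add("Mφ", "Monocyte")

    def test_ontology_csv_and_xml_readers_agree(self, tmp_path):
        (tmp_path / "o.csv").write_text(
            "raw,canonical,domain\nMφ,Macrophage,node\ngut,intestine,location\n")
        (tmp_path / "o.xml").write_text(
            "<ontology><term raw='Mφ' canonical='Macrophage'/>"
            "<term raw='gut' canonical='intestine' domain='location'/></ontology>")
        om_csv = OntologyMap.from_csv(tmp_path / "o.csv")
        om_xml = OntologyMap.from_xml(tmp_path / "o.xml")
        for om in (om_csv, om_xml):
            assert om.canonical("Mφ") == "Macrophage"
            assert om.canonical("gut", "location") == "intestine"
            assert om.canonical("gut") == "gut"  # domain separation
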