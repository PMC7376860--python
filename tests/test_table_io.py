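"""Table loading diagnostics, RDF round-trips and store diffing."""

import warnings

import pytest

from prockb import (TableFormatError, apply_rules_to_fixpoint, diff_kb,
                    export_ontology, export_table, simple_enzyme_fixture,
                    load_instantiation_table, load_ontology,
                    load_rule_catalog)
from prockb.kb import DECLARED
from prockb.table_io import LoadReport


class TestLoad:
    def test_simple_enzyme_fixture_counts(self, simple_enzyme_kb):
        m = simple_enzyme_kb.metrics()
        assert m.individuals == 10
        assert m.declared_class_assertions == 10
        assert m.declared_property_assertions == 9
        assert m.inferred_class_assertions == 0

    def test_empty_table_gives_empty_kb(self, schema):
        kb = load_instantiation_table("subject,kind,predicate,object\n", schema)
        assert kb.metrics().individuals == 0

    def test_tab_delimiter_autodetected(self, schema):
        text = "subject\tkind\tpredicate\tobject\nX\ttype\tMetabolite\t\n"
        kb = load_instantiation_table(text, schema)
        assert kb.has_class_assertion("X", "Metabolite")

    def test_unknown_class_reports_line_number(self, schema):
        text = "subject,kind,predicate,object\nX,type,NoSuchClass,\n"
        with pytest.raises(TableFormatError, match=":2"):
            load_instantiation_table(text, schema)

    def test_duplicate_rows_deduplicated_with_warning(self, schema):
        text = ("subject,kind,predicate,object\n"
                "X,type,Metabolite,\nX,type,Metabolite,\n")
        rep = LoadReport()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            kb = load_instantiation_table(text, schema, report=rep)
        assert kb.metrics().declared_class_assertions == 1
        assert any("duplicate" in str(w.message) for w in caught)
        assert any("duplicate" in w for w in rep.warnings)

    def test_non_assertable_property_warns_then_errors_in_strict(self, schema):
        text = ("subject,kind,predicate,object\n"
                "a,property,has_function,b\n")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            kb = load_instantiation_table(text, schema)
        assert any("not user-assertable" in str(w.message) for w in caught)
        assert kb.has_property_assertion("a", "has_function", "b")
        with pytest.raises(TableFormatError, match="not user-assertable"):
            load_instantiation_table(text, schema, strict=True)

    def test_identifiers_trimmed_but_spaces_preserved(self, schema):
        text = ("subject,kind,predicate,object\n"
                " Phosphoglycerate kinase 1 ,type,SimpleProtein,\n")
        kb = load_instantiation_table(text, schema)
        assert kb.has_individual("Phosphoglycerate kinase 1")

    def test_row_conservation(self, schema):
        """Declared counts equal non-duplicate row counts per kind."""
        text = simple_enzyme_fixture()
        rep = LoadReport()
        kb = load_instantiation_table(text, schema, report=rep)
        m = kb.metrics()
        assert rep.class_assertions == m.declared_class_assertions
        assert rep.property_assertions == m.declared_property_assertions


class TestTableRoundTrip:
    def test_export_reload_row_set_identical(self, schema):
        from prockb.fixtures import NetworkParams, generate_network
        net = generate_network(NetworkParams(
            n_metabolic_reactions=5, n_complex_assemblies=3,
            n_ptm_reactions=4, pathway_length=(2, 3), seed=2), schema)
        kb = load_instantiation_table(net.table, schema)
        text = export_table(kb)
        kb2 = load_instantiation_table(text, schema)
        assert kb.assertion_keys() == kb2.assertion_keys()
        # and a second round trip is byte-stable
        assert export_table(kb2) == text


class TestOntologyExport:
    def test_trig_round_trip_preserves_status(self, tmp_path, simple_enzyme_kb, rules):
        apply_rules_to_fixpoint(simple_enzyme_kb, rules)
        path = tmp_path / "out.trig"
        export_ontology(simple_enzyme_kb, path, format="trig")
        clone = load_ontology(path, simple_enzyme_kb.schema)
        assert clone.assertion_keys() == simple_enzyme_kb.assertion_keys()
        for a in simple_enzyme_kb.class_assertions():
            assert clone.get_class_assertion(*a.key).status == a.status

    def test_imported_class_keeps_original_iri(self, tmp_path, simple_enzyme_kb):
        path = tmp_path / "out.ttl"
        export_ontology(simple_enzyme_kb, path, format="turtle")
        text = path.read_text()
        assert "http://purl.obolibrary.org/obo/GO_0016301" in text  # kinase activity
        assert "http://purl.obolibrary.org/obo/CHEBI_25212" in text  # metabolite

    def test_triple_count_matches_store_arithmetic(self, tmp_path, simple_enzyme_kb):
        import rdflib
        path = tmp_path / "out.trig"
        export_ontology(simple_enzyme_kb, path, format="trig")
        ds = rdflib.Dataset()
        ds.parse(str(path), format="trig")
        ns = simple_enzyme_kb.schema.namespace
        declared = ds.graph(rdflib.URIRef(ns + "declared"))
        n_assert = len(list(simple_enzyme_kb.class_assertions())) + \
            len(list(simple_enzyme_kb.property_assertions()))
        # declared graph = assertions + (type NamedIndividual + label) each
        assert len(declared) == n_assert + 2 * len(simple_enzyme_kb.individuals)


class TestDiff:
    def test_self_diff_empty(self, simple_enzyme_kb):
        assert diff_kb(simple_enzyme_kb, simple_enzyme_kb).is_empty()

    def test_pre_post_diff_equals_ledger(self, schema, rules, simple_enzyme_kb):
        pre = simple_enzyme_kb.copy()
        ledger = apply_rules_to_fixpoint(simple_enzyme_kb, rules)
        report = diff_kb(pre, simple_enzyme_kb)
        assert report.only_a == []
        got = {(e.kind,) + e.key for e in report.only_b}
        assert got == ledger.keys()

    def test_removing_function_rule_only_drops_its_provenance(
            self, schema, rules, simple_enzyme_kb):
        """Without the function-assignment rule, exactly the has_function
        assertions (and their inverses) disappear."""
        full = simple_enzyme_kb.copy()
        apply_rules_to_fixpoint(full, rules)
        reduced_rules = [r for r in rules if r.id != "R27"]
        reduced = simple_enzyme_kb.copy()
        apply_rules_to_fixpoint(reduced, reduced_rules)
        report = diff_kb(full, reduced)
        assert report.only_b == []
        assert {e.key[1] for e in report.only_a} == \
            {"has_function", "function_of"}
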