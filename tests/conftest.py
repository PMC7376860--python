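import pytest

from prockb import (EngineConfig, KnowledgeBase, apply_rules_to_fixpoint,
                    build_core_schema, simple_enzyme_fixture, rubisco_fixture,
                    load_instantiation_table, load_rule_catalog)


@pytest.fixture(scope="session")
def schema():
    return build_core_schema()


@pytest.fixture(scope="session")
def rules(schema):
    return load_rule_catalog(None, schema)


@pytest.fixture()
def empty_kb(schema):
    return KnowledgeBase(schema)


@pytest.fixture()
def simple_enzyme_kb(schema):
    return load_instantiation_table(simple_enzyme_fixture(), schema)


@pytest.fixture()
def rubisco_kb(schema):
    return load_instantiation_table(rubisco_fixture(), schema)


@pytest.fixture()
def simple_enzyme_saturated(simple_enzyme_kb, rules):
    ledger = apply_rules_to_fixpoint(simple_enzyme_kb, rules)
    return simple_enzyme_kb, ledger


@pytest.fixture()
def rubisco_saturated(rubisco_kb, rules):
    ledger = apply_rules_to_fixpoint(rubisco_kb, rules)
    return rubisco_kb, ledger
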