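"""Worked-example fixtures and a seeded synthetic-network generator.

Two literal fixtures ship here: a simple-enzyme metabolic reaction (the
phosphoglycerate kinase step of the Calvin cycle, with the Mg-ATP
complexation subgraph needed for molecular-composition inference) and the
RuBisCO assembly/activation mini-network (chaperoned complex assembly,
carbamylation, magnesium binding, and the two catalytic reactions of the
holoenzyme).

``generate_network`` emits instantiation tables containing the structural
motifs the rule catalog consumes — enzymatic metabolic reactions,
spontaneous and ATP-dependent protein complex assemblies, post-translational
modifications, and precedes-ordered pathways — together with a ground-truth
ledger of every assertion saturation is expected to add.  The ledger is
built constructively while generating (per-motif rule consequences plus an
independent schema-closure pass), never by running the engine, so it can
serve as an oracle for the engine.  Generator distributions are uniform
draws and carry no biological claim; default sizes mirror a single
pathway-scale curation (24 enzymatic metabolic reactions, 58
post-translational modifications).

Reserved individual ids ``ATP``, ``ADP``, ``P`` and ``Mg2+`` have fixed
typing because the ATP-dependent assembly rule names ADP and P as
constants.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import GenerationError
from .kb import KnowledgeBase
from .schema import Schema, build_core_schema
from .table_io import HEADER, load_instantiation_table

#: reserved ids with fixed declared typing (see module docstring)
RESERVED_TYPES = {
    "ATP": "Metabolite",
    "ADP": "Metabolite",
    "P": "Metabolite",
    "Mg2+": "MetalIon",
}

# (declared activity class, enzyme classes the rules assign, process class)
_REACTION_VARIANTS = (
    ("OxidoreductaseActivity", ("Oxidoreductase",), "MetabolicOxidoreduction"),
    ("TransferaseActivity", ("Transferase",), "MetabolicTransference"),
    ("HydrolaseActivity", ("Hydrolase",), "MetabolicHydrolysis"),
    ("LyaseActivity", ("Lyase",), "MetabolicLysis"),
    ("IsomeraseActivity", ("Isomerase",), "MetabolicIsomerization"),
    ("LigaseActivity", ("Ligase",), "MetabolicLigation"),
    # a kinase activity is a transferase activity, so both rules fire
    ("KinaseActivity", ("Kinase", "Transferase"), "Phosphorylation"),
)


def _csv(rows: list[tuple[str, str, str, str]]) -> str:
    import csv as _csvmod
    import io
    buf = io.StringIO()
    w = _csvmod.writer(buf, lineterminator="\n")
    w.writerow(HEADER)
    w.writerows(rows)
    return buf.getvalue()


# -- literal worked examples -------------------------------------------------


def simple_enzyme_fixture() -> str:
    """Simple-enzyme fixture: phosphorylation of 3-phosphoglycerate.

    The central reaction carries exactly six declared property assertions
    (two has_input, two has_output, one mediated_by, one requires); the
    Mg-ATP complexation subgraph supplies the subcomponent structure that
    the composition rules expose.
    """
    rows = [
        ("phosphorylation of 3-PGA", "type", "MetabolicTransference", ""),
        ("Mg-ATP", "type", "Non-geneProduct", ""),
        ("3-Phosphoglycerate", "type", "Non-geneProduct", ""),
        ("Mg-ADP", "type", "Non-geneProduct", ""),
        ("1,3-Biphosphoglycerate", "type", "Non-geneProduct", ""),
        ("Phosphoglycerate kinase 1", "type", "SimpleProtein", ""),
        ("Phosphoglycerate kinase activity", "type", "KinaseActivity", ""),
        ("complexation of Mg-ATP", "type", "SmallMoleculeComplexation", ""),
        ("Mg2+", "type", "MetalIon", ""),
        ("ATP", "type", "Metabolite", ""),
        ("phosphorylation of 3-PGA", "property", "has_input", "Mg-ATP"),
        ("phosphorylation of 3-PGA", "property", "has_input", "3-Phosphoglycerate"),
        ("phosphorylation of 3-PGA", "property", "has_output", "Mg-ADP"),
        ("phosphorylation of 3-PGA", "property", "has_output", "1,3-Biphosphoglycerate"),
        ("phosphorylation of 3-PGA", "property", "mediated_by", "Phosphoglycerate kinase 1"),
        ("phosphorylation of 3-PGA", "property", "requires", "Phosphoglycerate kinase activity"),
        ("complexation of Mg-ATP", "property", "has_input", "Mg2+"),
        ("complexation of Mg-ATP", "property", "has_input", "ATP"),
        ("complexation of Mg-ATP", "property", "has_output", "Mg-ATP"),
    ]
    return _csv(rows)


def rubisco_fixture() -> str:
    """RuBisCO assembly and activation mini-network.

    Chaperone-mediated assembly of the 8L8S complex from RBCL/RBCS,
    carbamylation by CO2, magnesium binding yielding the holoenzyme, and
    the holoenzyme's carboxylation and oxygenation reactions; the three
    activation steps form a precedes-ordered activation pathway.
    """
    rows = [
        ("RBCL", "type", "SimpleProtein", ""),
        ("RBCS", "type", "SimpleProtein", ""),
        ("RBCX", "type", "SimpleProtein", ""),
        ("RAF1", "type", "SimpleProtein", ""),
        ("Mg2+", "type", "MetalIon", ""),
        ("CO2", "type", "Metabolite", ""),
        ("O2", "type", "Metabolite", ""),
        ("D-ribulose 1,5-bisphosphate", "type", "Non-geneProduct", ""),
        ("3-Phosphoglycerate", "type", "Non-geneProduct", ""),
        ("2-Phosphoglycolate", "type", "Non-geneProduct", ""),
        ("RuBisCO (8L8S)", "type", "GeneProduct", ""),
        ("carbamylated RuBisCO", "type", "GeneProduct", ""),
        ("RuBisCO holoenzyme", "type", "GeneProduct", ""),
        ("RuBisCO assembly", "type", "ProteinComplexAssembly", ""),
        ("carbamylation of RuBisCO", "type", "ProteinCarbamylation", ""),
        ("RuBisCO-Mg complexation", "type", "ProteinLigandBinding", ""),
        ("carboxylation of D-ribulose 1,5-bisphosphate", "type", "Carboxylation", ""),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "type", "MetabolicOxidoreduction", ""),
        ("ribulose-bisphosphate carboxylase activity", "type", "CarboxylaseActivity", ""),
        ("monooxygenase activity", "type", "MonooxygenaseActivity", ""),
        ("RuBisCO chaperoning activity", "type", "ChaperoningActivity", ""),
        ("RuBisCO activation pathway", "type", "ActivationPathway", ""),
        ("RuBisCO assembly", "property", "has_input", "RBCL"),
        ("RuBisCO assembly", "property", "has_input", "RBCS"),
        ("RuBisCO assembly", "property", "mediated_by", "RBCX"),
        ("RuBisCO assembly", "property", "mediated_by", "RAF1"),
        ("RuBisCO assembly", "property", "requires", "RuBisCO chaperoning activity"),
        ("RuBisCO assembly", "property", "has_output", "RuBisCO (8L8S)"),
        ("carbamylation of RuBisCO", "property", "has_input", "RuBisCO (8L8S)"),
        ("carbamylation of RuBisCO", "property", "has_input", "CO2"),
        ("carbamylation of RuBisCO", "property", "has_output", "carbamylated RuBisCO"),
        ("RuBisCO-Mg complexation", "property", "has_input", "carbamylated RuBisCO"),
        ("RuBisCO-Mg complexation", "property", "has_input", "Mg2+"),
        ("RuBisCO-Mg complexation", "property", "has_output", "RuBisCO holoenzyme"),
        ("carboxylation of D-ribulose 1,5-bisphosphate", "property", "has_input", "D-ribulose 1,5-bisphosphate"),
        ("carboxylation of D-ribulose 1,5-bisphosphate", "property", "has_input", "CO2"),
        ("carboxylation of D-ribulose 1,5-bisphosphate", "property", "has_output", "3-Phosphoglycerate"),
        ("carboxylation of D-ribulose 1,5-bisphosphate", "property", "mediated_by", "RuBisCO holoenzyme"),
        ("carboxylation of D-ribulose 1,5-bisphosphate", "property", "requires", "ribulose-bisphosphate carboxylase activity"),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "property", "has_input", "D-ribulose 1,5-bisphosphate"),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "property", "has_input", "O2"),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "property", "has_output", "2-Phosphoglycolate"),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "property", "has_output", "3-Phosphoglycerate"),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "property", "mediated_by", "RuBisCO holoenzyme"),
        ("oxygenation of D-ribulose 1,5-bisphosphate", "property", "requires", "monooxygenase activity"),
        ("RuBisCO activation pathway", "property", "starts_with", "RuBisCO assembly"),
        ("RuBisCO activation pathway", "property", "has_intermediary_process", "carbamylation of RuBisCO"),
        ("RuBisCO activation pathway", "property", "ends_with", "RuBisCO-Mg complexation"),
        ("RuBisCO assembly", "property", "precedes", "carbamylation of RuBisCO"),
        ("carbamylation of RuBisCO", "property", "precedes", "RuBisCO-Mg complexation"),
    ]
    return _csv(rows)


def fixture_kb(table_text: str, schema: Schema | None = None) -> KnowledgeBase:
    """Load a fixture table into a knowledge base over the core schema."""
    if schema is None:
        schema = build_core_schema()
    return load_instantiation_table(table_text, schema)


# -- synthetic generator -----------------------------------------------------


@dataclass(frozen=True)
class NetworkParams:
    """Composition of a generated network.

    Defaults emulate one curated pathway's worth of content: 24 enzymatic
    metabolic reactions and 58 post-translational modifications, a handful
    of complex assemblies, one precedes-ordered pathway.
    """

    n_metabolic_reactions: int = 24
    n_complex_assemblies: int = 10
    subunits_per_complex: tuple[int, int] = (2, 4)
    fraction_atp_dependent: float = 0.25
    n_pathways: int = 1
    pathway_length: tuple[int, int] = (4, 10)
    n_ptm_reactions: int = 58
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_metabolic_reactions", "n_complex_assemblies",
                     "n_pathways", "n_ptm_reactions"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        for name in ("subunits_per_complex", "pathway_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise GenerationError(f"{name} range {lo}..{hi} is empty")
        if not 0.0 <= self.fraction_atp_dependent <= 1.0:
            raise GenerationError("fraction_atp_dependent must be in [0, 1]")


@dataclass
class SyntheticNetwork:
    """Generated table plus the constructively-computed expected inferences."""

    params: NetworkParams
    table: str
    declared_class_assertions: list = field(default_factory=list)
    declared_property_assertions: list = field(default_factory=list)
    expected_class_assertions: set = field(default_factory=set)
    expected_property_assertions: set = field(default_factory=set)

    @property
    def individuals(self) -> set:
        inds = {k[0] for k in self.declared_class_assertions}
        for s, _p, o in self.declared_property_assertions:
            inds.add(s)
            inds.add(o)
        return inds


def _schema_closure(schema: Schema, class_facts: set, prop_facts: set
                    ) -> tuple[set, set]:
    """Independent fixpoint of subclass/sub-property/inverse/domain/range
    entailments (naive iterate-until-stable; the oracle side of the
    generator ledger)."""
    classes = set(class_facts)
    props = set(prop_facts)
    changed = True
    while changed:
        changed = False
        for ind, cls in list(classes):
            for sup in schema.superclasses(cls):
                if (ind, sup) not in classes:
                    classes.add((ind, sup))
                    changed = True
        for s, p, o in list(props):
            pdef = schema.properties[p]
            new_props = []
            if pdef.super_property:
                new_props.append((s, pdef.super_property, o))
            if pdef.inverse:
                new_props.append((o, pdef.inverse, s))
            for t in new_props:
                if t not in props:
                    props.add(t)
                    changed = True
            for ind, cls in ((s, pdef.domain), (o, pdef.range)):
                if cls and (ind, cls) not in classes:
                    classes.add((ind, cls))
                    changed = True
    return classes, props


class _Builder:
    def __init__(self, params: NetworkParams, schema: Schema):
        self.params = params
        self.schema = schema
        self.rng = random.Random(params.seed)
        self.rows: list[tuple[str, str, str, str]] = []
        self.decl_class: list[tuple[str, str]] = []
        self.decl_prop: list[tuple[str, str, str]] = []
        # rule-level expected facts (pre-closure)
        self.rule_class: set[tuple[str, str]] = set()
        self.rule_prop: set[tuple[str, str, str]] = set()
        self._reserved_used: set[str] = set()

    def declare_type(self, ind: str, cls: str) -> None:
        self.rows.append((ind, "type", cls, ""))
        self.decl_class.append((ind, cls))

    def declare_prop(self, s: str, p: str, o: str) -> None:
        self.rows.append((s, "property", p, o))
        self.decl_prop.append((s, p, o))

    def reserve(self, ind: str) -> None:
        if ind not in self._reserved_used:
            self._reserved_used.add(ind)
            self.declare_type(ind, RESERVED_TYPES[ind])

    # -- motifs -------------------------------------------------------------

    def metabolic_reaction(self, rid: str, inputs, outputs) -> None:
        activity_cls, enzyme_classes, process_cls = \
            _REACTION_VARIANTS[self.rng.randrange(len(_REACTION_VARIANTS))]
        enzyme = f"enzyme {rid}"
        activity = f"activity of {rid}"
        self.declare_type(rid, process_cls)
        self.declare_type(enzyme, "SimpleProtein")
        self.declare_type(activity, activity_cls)
        for m in inputs:
            self.declare_prop(rid, "has_input", m)
        for m in outputs:
            self.declare_prop(rid, "has_output", m)
        self.declare_prop(rid, "mediated_by", enzyme)
        self.declare_prop(rid, "requires", activity)
        # rule consequences
        self.rule_class.add((rid, "MediatedProcess"))          # R1
        self.rule_class.add((rid, "EnzymaticReaction"))        # R5
        self.rule_class.add((enzyme, "Enzyme"))                # R5
        for m in list(inputs) + list(outputs):
            self.rule_class.add((m, "Metabolite"))             # R3/R4
        for cls in enzyme_classes:
            self.rule_class.add((enzyme, cls))                 # R15-R21
        self.rule_prop.add((enzyme, "has_function", activity))  # R27

    def fresh_metabolite(self, name: str) -> str:
        self.declare_type(name, "Non-geneProduct")
        return name

    def plain_reaction(self, idx: int) -> None:
        rid = f"reaction {idx:04d}"
        n_in = self.rng.randint(1, 2)
        n_out = self.rng.randint(1, 2)
        inputs = [self.fresh_metabolite(f"metabolite {rid} in{j}")
                  for j in range(n_in)]
        outputs = [self.fresh_metabolite(f"metabolite {rid} out{j}")
                   for j in range(n_out)]
        self.metabolic_reaction(rid, inputs, outputs)

    def assembly(self, idx: int) -> None:
        aid = f"assembly {idx:04d}"
        complex_id = f"complex {idx:04d}"
        k = self.rng.randint(*self.params.subunits_per_complex)
        subunits = [f"subunit {idx:04d}.{j}" for j in range(k)]
        atp_dependent = self.rng.random() < self.params.fraction_atp_dependent
        self.declare_type(aid, "ProteinComplexAssembly")
        for s in subunits:
            self.declare_type(s, "SimpleProtein")
        self.declare_type(complex_id, "GeneProduct")
        for s in subunits:
            self.declare_prop(aid, "has_input", s)
        self.declare_prop(aid, "has_output", complex_id)
        if atp_dependent:
            for r in ("ATP", "ADP", "P"):
                self.reserve(r)
            self.declare_prop(aid, "has_input", "ATP")
            self.declare_prop(aid, "has_output", "ADP")
            self.declare_prop(aid, "has_output", "P")
        # rule consequences (R10/R11/R12, same heads either way; by-products
        # and ATP are excluded by the DifferentFrom guards)
        self.rule_class.add((complex_id, "ProteinComplex"))
        for s in subunits:
            self.rule_class.add((s, "ProteinComplexSubunit"))
            self.rule_prop.add((complex_id, "has_molecular_part", s))

    def ptm(self, idx: int) -> None:
        tid = f"ptm {idx:04d}"
        target = f"target protein {idx:04d}"
        modified = f"target protein {idx:04d} (phosphorylated)"
        mediator = f"protein kinase {idx:04d}"
        activity = f"activity of {tid}"
        self.declare_type(tid, "ProteinPhosphorylation")
        self.declare_type(target, "SimpleProtein")
        self.declare_type(modified, "SimpleProtein")
        self.declare_type(mediator, "SimpleProtein")
        self.declare_type(activity, "KinaseActivity")
        self.declare_prop(tid, "has_input", target)
        self.declare_prop(tid, "has_output", modified)
        self.declare_prop(tid, "mediated_by", mediator)
        self.declare_prop(tid, "requires", activity)
        self.rule_class.add((tid, "MediatedProcess"))           # R1
        self.rule_class.add((mediator, "Kinase"))               # R21
        self.rule_class.add((mediator, "Transferase"))          # R16
        self.rule_prop.add((mediator, "has_function", activity))  # R27
        self.rule_prop.add((target, "interacts_with", mediator))  # R25

    def pathway(self, idx: int, length: int) -> None:
        pw = f"pathway {idx:02d}"
        self.declare_type(pw, "MetabolicPathway")
        steps = []
        chain = [self.fresh_metabolite(f"chain {idx:02d}.{j}")
                 for j in range(length + 1)]
        cofactors = []
        for j in range(length):
            rid = f"pathway {idx:02d} step {j:02d}"
            cof = self.fresh_metabolite(f"cofactor {idx:02d}.{j}")
            cofactors.append(cof)
            self.metabolic_reaction(rid, [chain[j], cof], [chain[j + 1]])
            steps.append(rid)
        self.declare_prop(pw, "starts_with", steps[0])
        for rid in steps[1:-1]:
            self.declare_prop(pw, "has_intermediary_process", rid)
        if len(steps) > 1:
            self.declare_prop(pw, "ends_with", steps[-1])
        else:
            self.declare_prop(pw, "ends_with", steps[0])
        for a, b in zip(steps, steps[1:]):
            self.declare_prop(a, "precedes", b)
        # pathway participants: chain endpoints, cofactors and mediators;
        # intermediates (output of step j, input of step j+1) are excluded
        participants = {chain[0], chain[-1], *cofactors}
        participants |= {f"enzyme {rid}" for rid in steps}
        for x in participants:
            self.rule_prop.add((pw, "has_participant", x))

    # -- assembly of the whole network --------------------------------------

    def build(self) -> SyntheticNetwork:
        p = self.params
        lengths = [self.rng.randint(*p.pathway_length)
                   for _ in range(p.n_pathways)]
        if sum(lengths) > p.n_metabolic_reactions:
            raise GenerationError(
                f"pathways need {sum(lengths)} reactions but only "
                f"{p.n_metabolic_reactions} metabolic reactions requested")
        n_plain = p.n_metabolic_reactions - sum(lengths)
        for i, length in enumerate(lengths):
            self.pathway(i, length)
        for i in range(n_plain):
            self.plain_reaction(i)
        for i in range(p.n_complex_assemblies):
            self.assembly(i)
        for i in range(p.n_ptm_reactions):
            self.ptm(i)
        declared_c = set(self.decl_class)
        declared_p = set(self.decl_prop)
        closed_c, closed_p = _schema_closure(
            self.schema, declared_c | self.rule_class,
            declared_p | self.rule_prop)
        return SyntheticNetwork(
            params=p,
            table=_csv(self.rows),
            declared_class_assertions=list(self.decl_class),
            declared_property_assertions=list(self.decl_prop),
            expected_class_assertions=closed_c - declared_c,
            expected_property_assertions=closed_p - declared_p,
        )


def generate_network(params: NetworkParams,
                     schema: Schema | None = None) -> SyntheticNetwork:
    """Generate an instantiation table plus its expected-inference ledger.

    Deterministic: the same params (including seed) produce byte-identical
    table text and an identical ledger.
    """
    params.validate()
    if schema is None:
        schema = build_core_schema()
    return _Builder(params, schema).build()
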