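"""Forward-chaining saturation of a knowledge base.

The engine materialises, to fixpoint, everything entailed by

* the schema: subclass subsumption, sub-property propagation, inverse
  completion, and domain/range typing of property assertions;
* the rule catalog (safe positive Horn rules, no value invention);
* the pathway-participant pass: a pathway acquires ``has_participant``
  links to the inputs, outputs and mediators of its subprocesses, excluding
  transient intermediates (entities produced by one reaction and consumed
  by the immediately following one along the declared ``precedes`` chain).

Evaluation is semi-naive: each newly derived assertion is joined once
against the store through the rule atoms it can instantiate, so rule bodies
are never re-evaluated against the full cross-product.  Because all rules
are positive and no new individuals are ever created, the Herbrand base is
finite and saturation terminates; monotonicity and order-independence
follow from positivity (the fixpoint is the least model).

Every inferred assertion carries the id of the rule or entailment that
first produced it (``subclass``, ``subproperty``, ``inverse``, ``domain``,
``range``, ``pathway`` or a catalog rule id).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import StructuralError
from .kb import INFERRED, KnowledgeBase, PropertyAssertion
from .rules import Atom, Rule, instantiate_head, join_atoms, match_rule


@dataclass(frozen=True)
class InferenceRecord:
    """One materialised assertion: ('class', ind, cls) or ('prop', s, p, o)."""

    kind: str
    key: tuple
    provenance: str


@dataclass
class InferenceLedger:
    records: list[InferenceRecord] = field(default_factory=list)

    def add(self, kind: str, key: tuple, provenance: str) -> None:
        self.records.append(InferenceRecord(kind, key, provenance))

    def keys(self) -> set[tuple]:
        return {(r.kind,) + r.key for r in self.records}

    def by_provenance(self) -> Counter:
        return Counter(r.provenance for r in self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class EngineConfig:
    """Saturation switches.

    symmetric_interactions: also materialise interacts_with(y, x) for every
    interacts_with(x, y) (off by default: the published rule is directed).
    pathway_inference: run the pathway-participant pass.
    """

    symmetric_interactions: bool = False
    pathway_inference: bool = True


class _Saturator:
    def __init__(self, kb: KnowledgeBase, rules: Sequence[Rule],
                 config: EngineConfig):
        self.kb = kb
        self.rules = list(rules)
        self.config = config
        self.ledger = InferenceLedger()
        self.queue: deque = deque()
        self._build_triggers()

    def _build_triggers(self) -> None:
        # The subsumption closure is materialised as facts arrive, so a
        # class atom on C only needs to fire when the fact (i, C) itself is
        # added (the superclass memberships of a new typing each arrive as
        # their own facts and re-trigger); bodies are then evaluated against
        # exact class membership.
        self.class_triggers: dict[str, list[tuple[Rule, int]]] = {}
        self.prop_triggers: dict[str, list[tuple[Rule, int]]] = {}
        for rule in self.rules:
            rule.validate()
            for idx, atom in enumerate(rule.body):
                if atom.kind == "class":
                    self.class_triggers.setdefault(atom.predicate, []).append((rule, idx))
                elif atom.kind == "property":
                    self.prop_triggers.setdefault(atom.predicate, []).append((rule, idx))

    # -- fact addition -------------------------------------------------------

    def add_class(self, ind: str, cls: str, provenance: str) -> None:
        if self.kb.assert_class(ind, cls, INFERRED, provenance):
            self.ledger.add("class", (ind, cls), provenance)
            self.queue.append(("class", ind, cls))

    def add_prop(self, s: str, p: str, o: str, provenance: str) -> None:
        if self.kb.assert_property(s, p, o, INFERRED, provenance):
            self.ledger.add("prop", (s, p, o), provenance)
            self.queue.append(("prop", s, p, o))

    # -- processing ----------------------------------------------------------

    def seed(self) -> None:
        for a in list(self.kb.class_assertions()):
            self.queue.append(("class", a.individual, a.class_id))
        for a in list(self.kb.property_assertions()):
            self.queue.append(("prop", a.subject, a.property_id, a.object))

    def drain(self) -> None:
        while self.queue:
            fact = self.queue.popleft()
            if fact[0] == "class":
                self._process_class(fact[1], fact[2])
            else:
                self._process_prop(fact[1], fact[2], fact[3])

    def _process_class(self, ind: str, cls: str) -> None:
        for parent in self.kb.schema.classes[cls].parents:
            self.add_class(ind, parent, "subclass")
        for rule, idx in self.class_triggers.get(cls, ()):
            self._fire(rule, idx, {rule.body[idx].args[0].name: ind}
                       if rule.body[idx].args[0].is_var else
                       ({} if rule.body[idx].args[0].name == ind else None))

    def _process_prop(self, s: str, p: str, o: str) -> None:
        pdef = self.kb.schema.properties[p]
        if pdef.super_property:
            self.add_prop(s, pdef.super_property, o, "subproperty")
        if pdef.inverse:
            self.add_prop(o, pdef.inverse, s, "inverse")
        if pdef.domain:
            self.add_class(s, pdef.domain, "domain")
        if pdef.range:
            self.add_class(o, pdef.range, "range")
        if self.config.symmetric_interactions and p == "interacts_with":
            self.add_prop(o, p, s, "symmetry")
        for rule, idx in self.prop_triggers.get(p, ()):
            atom = rule.body[idx]
            binding: Optional[dict] = {}
            for term, value in zip(atom.args, (s, o)):
                if term.is_var:
                    if binding.get(term.name, value) != value:
                        binding = None
                        break
                    binding[term.name] = value
                elif term.name != value:
                    binding = None
                    break
            self._fire(rule, idx, binding)

    def _fire(self, rule: Rule, idx: int, binding: Optional[dict]) -> None:
        if binding is None:
            return
        rest = rule.body[:idx] + rule.body[idx + 1:]
        for b in join_atoms(self.kb, rest, binding, exact=True):
            for ground in instantiate_head(rule, b):
                if ground[0] == "class":
                    self.add_class(ground[1], ground[2], rule.id)
                else:
                    self.add_prop(ground[1], ground[2], ground[3], rule.id)

    # -- pathway pass --------------------------------------------------------

    def pathway_pass(self) -> int:
        added = 0
        for pw, parts in pathway_participants(self.kb).items():
            for x in parts:
                before = len(self.ledger)
                self.add_prop(pw, "has_participant", x, "pathway")
                added += len(self.ledger) - before
        return added

    def run(self) -> InferenceLedger:
        self.seed()
        self.drain()
        if self.config.pathway_inference:
            while True:
                before = len(self.ledger)
                self.pathway_pass()
                if len(self.ledger) == before:
                    break
                self.drain()
        return self.ledger


def apply_rules_to_fixpoint(kb: KnowledgeBase, ruleset: Sequence[Rule],
                            config: EngineConfig | None = None
                            ) -> InferenceLedger:
    """Saturate ``kb`` in place; returns the inference ledger.

    The result is the least fixpoint: independent of rule order, monotone
    (no assertion is ever removed or demoted) and idempotent.
    """
    sat = _Saturator(kb, ruleset, config or EngineConfig())
    return sat.run()


# convenient alias
saturate = apply_rules_to_fixpoint


def complete_inverses_and_superproperties(kb: KnowledgeBase) -> list[tuple]:
    """Property-schema closure only (no catalog rules, no typing).

    For every ``p(x, y)``: add ``super(x, y)`` for the transitive
    super-properties and ``inv(y, x)`` for inverses, marked inferred.
    Returns the keys of the added assertions.
    """
    added = []
    queue = deque((a.subject, a.property_id, a.object)
                  for a in kb.property_assertions())
    while queue:
        s, p, o = queue.popleft()
        pdef = kb.schema.properties[p]
        for target, prov in (((s, pdef.super_property, o), "subproperty"),
                             ((o, pdef.inverse, s), "inverse")):
            ts, tp, to = target
            if tp is None:
                continue
            if kb.assert_property(ts, tp, to, INFERRED, prov):
                added.append((ts, tp, to))
                queue.append((ts, tp, to))
    return added


def _subprocesses(kb: KnowledgeBase, pw: str) -> set[str]:
    procs: set[str] = set()
    for prop in ("starts_with", "ends_with", "has_intermediary_process",
                 "has_subprocess"):
        procs |= kb.objects(pw, prop)
    return procs


def _order_chain(kb: KnowledgeBase, pw: str, procs: set[str]) -> list[tuple[str, str]]:
    """The precedes edges among a pathway's subprocesses, validated as a
    chain (no cycle; at most one successor/predecessor per subprocess)."""
    edges = []
    succ: dict[str, str] = {}
    pred: dict[str, str] = {}
    for r in sorted(procs):
        for nxt in sorted(kb.objects(r, "precedes")):
            if nxt not in procs:
                continue
            if r in succ or nxt in pred:
                raise StructuralError(
                    f"pathway {pw!r}: precedes ordering branches at "
                    f"{r!r} -> {nxt!r}")
            succ[r] = nxt
            pred[nxt] = r
            edges.append((r, nxt))
    # cycle check: walk each maximal chain
    starts = [r for r in succ if r not in pred]
    visited: set[str] = set()
    for s in starts:
        node = s
        while node in succ:
            if node in visited:
                break
            visited.add(node)
            node = succ[node]
    if succ and (len(visited) < len(succ) or any(
            r in succ and r not in visited and r in pred for r in succ)):
        # some edge never reached from a chain start => cycle
        unreached = set(succ) - visited
        if unreached:
            raise StructuralError(
                f"pathway {pw!r}: precedes ordering contains a cycle "
                f"through {sorted(unreached)}")
    return edges


def pathway_participants(kb: KnowledgeBase) -> dict[str, set[str]]:
    """Participants each pathway should acquire.

    For every individual typed (a subclass of) ``Pathway``: the union of
    its subprocesses' inputs, outputs and mediators, minus every entity
    that is the output of a reaction and an input of the immediately
    following reaction (transient intermediates along ``precedes``).
    """
    result: dict[str, set[str]] = {}
    pathways: set[str] = set()
    for cls in kb.schema.subclasses("Pathway"):
        pathways |= kb.members_of(cls)
    for pw in sorted(pathways):
        procs = _subprocesses(kb, pw)
        if not procs:
            continue
        edges = _order_chain(kb, pw, procs)
        participants: set[str] = set()
        for r in procs:
            participants |= kb.objects(r, "has_input")
            participants |= kb.objects(r, "has_output")
            participants |= kb.objects(r, "mediated_by")
        transient: set[str] = set()
        for a, b in edges:
            transient |= kb.objects(a, "has_output") & kb.objects(b, "has_input")
        result[pw] = participants - transient
    return result


def infer_pathway_participants(kb: KnowledgeBase) -> list[PropertyAssertion]:
    """Materialise pathway participants (standalone pass); returns the new
    ``has_participant`` assertions."""
    added = []
    for pw, parts in pathway_participants(kb).items():
        for x in sorted(parts):
            if kb.assert_property(pw, "has_participant", x, INFERRED, "pathway"):
                added.append(kb.get_property_assertion(pw, "has_participant", x))
    return added
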