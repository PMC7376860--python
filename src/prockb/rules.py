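"""Declarative rules: safe Horn rules over class and property atoms.

A rule has a conjunctive body and a conjunctive head.  Atoms are written in
a compact SWRL-like text form inside the YAML catalog::

    body: ["MediatedProcess(?r)", "mediated_by(?r, ?p0)", "requires(?r, ?a)"]
    head: ["has_function(?p0, ?a)"]

``?name`` is a variable, anything else is an individual constant.  The
builtin ``DifferentFrom(x, y)`` evaluates as id inequality (unique-name
assumption).  Rules are *safe*: every head variable occurs in a positive
body atom; there is no negation and no value invention, so saturation
always terminates.

Class atoms are evaluated against the subsumption closure: an individual
typed ``Kinase`` satisfies a ``GeneProduct`` atom even before the closure
has been materialised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .errors import RuleDefinitionError
from .kb import KnowledgeBase
from .schema import Schema

DIFFERENT_FROM = "DifferentFrom"


@dataclass(frozen=True)
class Term:
    name: str
    is_var: bool

    def __str__(self):
        return ("?" + self.name) if self.is_var else self.name


def var(name: str) -> Term:
    return Term(name, True)


def const(name: str) -> Term:
    return Term(name, False)


@dataclass(frozen=True)
class Atom:
    """One body/head atom.

    kind is ``class`` (predicate = class id, one argument), ``property``
    (predicate = property id, two arguments) or ``different_from``.
    """

    kind: str
    predicate: str
    args: tuple[Term, ...]

    def variables(self) -> frozenset[str]:
        return frozenset(t.name for t in self.args if t.is_var)

    def __str__(self):
        return f"{self.predicate}({', '.join(str(a) for a in self.args)})"


_ATOM_RE = re.compile(r"^\s*([^()\s][^()]*?)\s*\(\s*(.*?)\s*\)\s*$")


def parse_term(text: str) -> Term:
    text = text.strip()
    if text.startswith("?"):
        name = text[1:]
        if not name:
            raise RuleDefinitionError(f"empty variable name in {text!r}")
        return var(name)
    return const(text)


def parse_atom(text: str, schema: Schema) -> Atom:
    m = _ATOM_RE.match(text)
    if not m:
        raise RuleDefinitionError(f"cannot parse atom {text!r}")
    pred, argstr = m.group(1), m.group(2)
    args = tuple(parse_term(a) for a in argstr.split(",")) if argstr else ()
    if pred == DIFFERENT_FROM:
        if len(args) != 2:
            raise RuleDefinitionError(f"{DIFFERENT_FROM} takes 2 arguments: {text!r}")
        return Atom("different_from", pred, args)
    if schema.has_property(pred):
        if len(args) != 2:
            raise RuleDefinitionError(f"property atom needs 2 arguments: {text!r}")
        return Atom("property", pred, args)
    if pred in schema:
        if len(args) != 1:
            raise RuleDefinitionError(f"class atom needs 1 argument: {text!r}")
        return Atom("class", pred, args)
    raise RuleDefinitionError(
        f"unknown predicate {pred!r} (not a class or property) in {text!r}")


@dataclass(frozen=True)
class Rule:
    id: str
    body: tuple[Atom, ...]
    head: tuple[Atom, ...]
    comment: str = ""

    def validate(self) -> None:
        bound = frozenset().union(*(a.variables() for a in self.body
                                    if a.kind != "different_from")) \
            if self.body else frozenset()
        for a in self.body:
            if a.kind == "different_from" and not a.variables() <= bound:
                raise RuleDefinitionError(
                    f"rule {self.id}: {DIFFERENT_FROM} variable not bound "
                    f"by a positive atom: {a}")
        for a in self.head:
            if a.kind == "different_from":
                raise RuleDefinitionError(
                    f"rule {self.id}: builtin atom not allowed in head")
            if not a.variables() <= bound:
                unbound = sorted(a.variables() - bound)
                raise RuleDefinitionError(
                    f"rule {self.id}: unsafe head variable(s) {unbound} in {a}")


def rule_from_dict(rec: dict, schema: Schema) -> Rule:
    try:
        rid = rec["id"]
    except (TypeError, KeyError):
        raise RuleDefinitionError(f"rule record without id: {rec!r}")
    body = tuple(parse_atom(a, schema) for a in rec.get("body", []))
    head = tuple(parse_atom(a, schema) for a in rec.get("head", []))
    if not head:
        raise RuleDefinitionError(f"rule {rid}: empty head")
    rule = Rule(rid, body, head, comment=rec.get("comment", ""))
    rule.validate()
    return rule


def load_rule_catalog(path: str | Path | None, schema: Schema) -> list[Rule]:
    """Load and validate a rule catalog; ``None`` loads the shipped one."""
    if path is None:
        path = default_catalog_path()
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    recs = cfg.get("rules", []) if isinstance(cfg, dict) else []
    rules = [rule_from_dict(rec, schema) for rec in recs]
    seen = set()
    for r in rules:
        if r.id in seen:
            raise RuleDefinitionError(f"duplicate rule id {r.id!r}")
        seen.add(r.id)
    return rules


def default_catalog_path() -> Path:
    return Path(__file__).parent / "data" / "rules.yaml"


# -- matching ----------------------------------------------------------------


def _class_members(kb: KnowledgeBase, class_id: str,
                   exact: bool = False):
    """Members of a class atom.

    ``exact=False`` evaluates against the subsumption closure (an
    individual typed Kinase satisfies a GeneProduct atom on an unsaturated
    store); ``exact=True`` trusts the store to be closure-materialised —
    the mode the saturation engine uses, where completeness follows from
    semi-naive re-triggering as superclass memberships are added.
    """
    if exact:
        return kb._cls2inds.get(class_id, ())
    members: set[str] = set()
    for sub in kb.schema.subclasses(class_id):
        members |= kb._cls2inds.get(sub, set())
    return members


def _satisfies_class(kb: KnowledgeBase, individual: str, class_id: str,
                     exact: bool = False) -> bool:
    carried = kb._ind2cls.get(individual, ())
    if exact:
        return class_id in carried
    subs = kb.schema.subclasses(class_id)
    return any(c in subs for c in carried)


def _objs(kb: KnowledgeBase, prop: str, subject: str):
    return kb._p_so.get(prop, _EMPTY).get(subject, ())


def _subs(kb: KnowledgeBase, prop: str, object: str):
    return kb._p_os.get(prop, _EMPTY).get(object, ())


_EMPTY: dict = {}


def _bind(term: Term, binding: dict) -> Optional[str]:
    """Resolved value of a term under a binding, or None if unbound."""
    if not term.is_var:
        return term.name
    return binding.get(term.name)


def match_atom(kb: KnowledgeBase, atom: Atom, binding: dict,
               exact: bool = False):
    """Yield extended bindings satisfying ``atom`` under ``binding``."""
    if atom.kind == "class":
        v = _bind(atom.args[0], binding)
        if v is not None:
            if _satisfies_class(kb, v, atom.predicate, exact):
                yield binding
            return
        for ind in _class_members(kb, atom.predicate, exact):
            yield {**binding, atom.args[0].name: ind}
        return
    if atom.kind == "property":
        s = _bind(atom.args[0], binding)
        o = _bind(atom.args[1], binding)
        if s is not None and o is not None:
            if kb.has_property_assertion(s, atom.predicate, o):
                yield binding
            return
        if s is not None:
            for obj in _objs(kb, atom.predicate, s):
                yield {**binding, atom.args[1].name: obj}
            return
        if o is not None:
            for sub in _subs(kb, atom.predicate, o):
                yield {**binding, atom.args[0].name: sub}
            return
        svar, ovar = atom.args[0].name, atom.args[1].name
        for sub, objs in kb._p_so.get(atom.predicate, {}).items():
            for obj in objs:
                b = {**binding, svar: sub}
                if svar == ovar:
                    if sub == obj:
                        yield b
                    continue
                b[ovar] = obj
                yield b
        return
    # different_from: both sides must be bound by now
    a = _bind(atom.args[0], binding)
    b = _bind(atom.args[1], binding)
    if a is not None and b is not None and a != b:
        yield binding


def _atom_cost(kb: KnowledgeBase, atom: Atom, binding: dict,
               exact: bool = False) -> float:
    """Rough candidate-count estimate used to order body atoms."""
    if atom.kind == "different_from":
        a = _bind(atom.args[0], binding)
        b = _bind(atom.args[1], binding)
        return 0.0 if (a is not None and b is not None) else float("inf")
    if atom.kind == "class":
        if _bind(atom.args[0], binding) is not None:
            return 0.0
        return float(len(_class_members(kb, atom.predicate, exact)))
    s = _bind(atom.args[0], binding)
    o = _bind(atom.args[1], binding)
    if s is not None and o is not None:
        return 0.0
    if s is not None:
        return float(len(_objs(kb, atom.predicate, s)))
    if o is not None:
        return float(len(_subs(kb, atom.predicate, o)))
    return float(sum(len(v) for v in kb._p_so.get(atom.predicate, {}).values()))


def join_atoms(kb: KnowledgeBase, atoms: Sequence[Atom], binding: dict,
               exact: bool = False):
    """Enumerate bindings satisfying all ``atoms``, cheapest-first order."""
    if not atoms:
        yield binding
        return
    remaining = list(atoms)
    best = min(range(len(remaining)),
               key=lambda i: _atom_cost(kb, remaining[i], binding, exact))
    atom = remaining.pop(best)
    for b in match_atom(kb, atom, binding, exact):
        yield from join_atoms(kb, remaining, b, exact)


def match_rule(rule: Rule, kb: KnowledgeBase) -> list[dict]:
    """All variable bindings satisfying the rule body.

    Each binding maps every body variable to an individual id; bindings are
    returned in a deterministic (sorted) order.  Class atoms are evaluated
    against the subsumption closure, so the result on an unsaturated store
    already reflects inherited typing.
    """
    rule.validate()
    seen = set()
    out = []
    varnames = sorted(frozenset().union(
        *(a.variables() for a in rule.body)) if rule.body else frozenset())
    for b in join_atoms(kb, rule.body, {}):
        key = tuple(b.get(v) for v in varnames)
        if key not in seen:
            seen.add(key)
            out.append({v: b[v] for v in varnames if v in b})
    out.sort(key=lambda b: tuple(b.get(v, "") for v in varnames))
    return out


def instantiate_head(rule: Rule, binding: dict):
    """Ground head atoms under a complete binding.

    Yields ``("class", individual, class_id)`` and
    ``("property", subject, property_id, object)`` tuples.
    """
    for atom in rule.head:
        if atom.kind == "class":
            yield ("class", _bind(atom.args[0], binding), atom.predicate)
        else:
            yield ("property", _bind(atom.args[0], binding), atom.predicate,
                   _bind(atom.args[1], binding))
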