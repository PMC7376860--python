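"""Terminological layer: class hierarchy, disjointness and property schema.

The schema is loaded from a YAML config file that is the single source of
truth for the ontology's classes and properties.  The shipped core config
(``prockb/data/core_schema.yaml``) describes a process-centered model of
metabolism: three mutually disjoint roots (``BiologicalProcess``,
``Participant``, ``Activity``), a hierarchy of process classes (metabolic
reactions, gene-product modifications, molecular interactions, pathways),
participant classes (gene products, metabolites, ions, complexes, active
entities) and activity classes (molecular functions, spontaneous
activities).  Classes imported from community ontologies (GO, ChEBI, NCI
Thesaurus) carry their original IRI so exports stay interoperable.

The subclass graph is a DAG (multiple parents are allowed, e.g. an
enzymatic reaction is both a metabolic process and a mediated process);
cycles are rejected at load time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import yaml

from .errors import SchemaCycleError, SchemaError, UnresolvedReferenceError

DEFAULT_NAMESPACE = "https://w3id.org/prockb#"

#: sources recognised for imported classes; anything else counts as native.
IMPORTED_SOURCES = ("GO", "CHEBI", "Thesaurus")


@dataclass(frozen=True)
class SchemaClass:
    """A named class of the terminological layer."""

    id: str
    label: str = ""
    parents: tuple[str, ...] = ()
    disjoint_with: tuple[str, ...] = ()
    source: str = "native"
    iri: Optional[str] = None

    @property
    def imported(self) -> bool:
        return self.source in IMPORTED_SOURCES


@dataclass(frozen=True)
class PropertyDef:
    """An object property: optional super-property, inverse, domain/range.

    ``asserted`` marks the user-assertable properties, i.e. the ones an
    instantiation table may declare directly; every other property is only
    ever materialised by the reasoner.
    """

    id: str
    super_property: Optional[str] = None
    inverse: Optional[str] = None
    domain: Optional[str] = None
    range: Optional[str] = None
    asserted: bool = False


@dataclass(frozen=True)
class DefinedClassAxiom:
    """A (partial) class definition: conjunction of property restrictions.

    Stored for documentation/validation; positive entailment directions are
    realised through the rule catalog under closed-world evaluation.
    """

    class_id: str
    condition: tuple[tuple[str, str, str, int], ...]  # (property, filler, quantifier, cardinality)
    direction: str = "necessary"  # or "necessary_and_sufficient"


class Schema:
    """Immutable view over the loaded class/property schema."""

    def __init__(self, classes: Sequence[SchemaClass],
                 properties: Sequence[PropertyDef],
                 defined_classes: Sequence[DefinedClassAxiom] = (),
                 namespace: str = DEFAULT_NAMESPACE):
        self.namespace = namespace
        self.classes: dict[str, SchemaClass] = {}
        for c in classes:
            if c.id in self.classes:
                raise SchemaError(f"duplicate class id {c.id!r}")
            self.classes[c.id] = c
        self.properties: dict[str, PropertyDef] = {}
        for p in properties:
            if p.id in self.properties:
                raise SchemaError(f"duplicate property id {p.id!r}")
            self.properties[p.id] = p
        self.defined_classes = tuple(defined_classes)
        self._validate()
        self._superclass_cache: dict[str, tuple[str, ...]] = {}
        self._disjoint_cache: dict[str, frozenset[str]] = {}

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for c in self.classes.values():
            for pid in c.parents:
                if pid not in self.classes:
                    raise UnresolvedReferenceError(pid, f"parent of class {c.id!r}")
            for did in c.disjoint_with:
                if did not in self.classes:
                    raise UnresolvedReferenceError(did, f"disjoint partner of {c.id!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for c in self.classes.values():
            for pid in c.parents:
                g.add_edge(c.id, pid)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise SchemaCycleError([a for a, _ in cycle] + [cycle[0][0]])
        self._parent_graph = g
        for p in self.properties.values():
            for ref, what in ((p.super_property, "super-property"),
                              (p.inverse, "inverse")):
                if ref is not None and ref not in self.properties:
                    raise UnresolvedReferenceError(ref, f"{what} of property {p.id!r}")
            for ref, what in ((p.domain, "domain"), (p.range, "range")):
                if ref is not None and ref not in self.classes:
                    raise UnresolvedReferenceError(ref, f"{what} of property {p.id!r}")
        for p in self.properties.values():
            if p.inverse is not None:
                q = self.properties[p.inverse]
                if q.inverse != p.id:
                    raise SchemaError(
                        f"inverse link not involutive: {p.id} -> {p.inverse} -> {q.inverse}")
        # sub-property links must form a forest (no cycles)
        sp = nx.DiGraph()
        sp.add_nodes_from(self.properties)
        for p in self.properties.values():
            if p.super_property:
                sp.add_edge(p.id, p.super_property)
        if not nx.is_directed_acyclic_graph(sp):
            raise SchemaError("sub-property links contain a cycle")
        for ax in self.defined_classes:
            if ax.class_id not in self.classes:
                raise UnresolvedReferenceError(ax.class_id, "defined-class axiom")
            for prop, filler, _q, _n in ax.condition:
                if prop not in self.properties:
                    raise UnresolvedReferenceError(prop, f"axiom on {ax.class_id!r}")
                if filler not in self.classes:
                    raise UnresolvedReferenceError(filler, f"axiom on {ax.class_id!r}")

    # -- queries ------------------------------------------------------------

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def has_property(self, prop_id: str) -> bool:
        return prop_id in self.properties

    def roots(self) -> list[str]:
        return sorted(c.id for c in self.classes.values() if not c.parents)

    def superclasses(self, class_id: str) -> tuple[str, ...]:
        """Reflexive-transitive closure over parents.

        Order is topological (a class precedes its ancestors), ties broken
        by id, so the result is deterministic.
        """
        if class_id not in self.classes:
            raise KeyError(class_id)
        cached = self._superclass_cache.get(class_id)
        if cached is not None:
            return cached
        closure = set(nx.descendants(self._parent_graph, class_id))
        closure.add(class_id)
        sub = self._parent_graph.subgraph(closure)
        order = tuple(nx.lexicographical_topological_sort(sub))
        self._superclass_cache[class_id] = order
        return order

    def subclasses(self, class_id: str) -> frozenset[str]:
        """All classes subsumed by ``class_id`` (reflexive)."""
        if class_id not in self.classes:
            raise KeyError(class_id)
        closure = set(nx.ancestors(self._parent_graph, class_id))
        closure.add(class_id)
        return frozenset(closure)

    def _disjoint_partners(self, class_id: str) -> frozenset[str]:
        """Classes declared disjoint with any superclass of ``class_id``."""
        cached = self._disjoint_cache.get(class_id)
        if cached is not None:
            return cached
        partners: set[str] = set()
        for sup in self.superclasses(class_id):
            partners.update(self.classes[sup].disjoint_with)
            # symmetry: collect classes that declare `sup` as their partner
            for other in self.classes.values():
                if sup in other.disjoint_with:
                    partners.add(other.id)
        result = frozenset(partners)
        self._disjoint_cache[class_id] = result
        return result

    def are_disjoint(self, a: str, b: str) -> bool:
        """True iff some superclass of ``a`` is declared disjoint with some
        superclass of ``b`` (inherited, symmetric disjointness)."""
        if a not in self.classes:
            raise KeyError(a)
        if b not in self.classes:
            raise KeyError(b)
        partners = self._disjoint_partners(a)
        return any(sup in partners for sup in self.superclasses(b))

    def subtree_census(self, root: str) -> tuple[int, int]:
        """(class count, max depth) of the subtree rooted at ``root``.

        Depth is the longest subclass path from ``root`` (root itself is at
        depth 0).
        """
        members = self.subclasses(root)
        depth = {root: 0}
        # longest-path over the reversed parent graph restricted to members
        sub = self._parent_graph.subgraph(members).reverse()
        for node in nx.topological_sort(sub):
            for child in sub.successors(node):
                d = depth.get(node, 0) + 1
                if d > depth.get(child, -1):
                    depth[child] = d
        return len(members), max(depth.values())

    def assertable_properties(self) -> list[str]:
        return sorted(p.id for p in self.properties.values() if p.asserted)

    # -- (de)serialisation --------------------------------------------------

    def to_config_dict(self) -> dict:
        classes = []
        for cid in sorted(self.classes):
            c = self.classes[cid]
            rec: dict = {"id": c.id}
            if c.label:
                rec["label"] = c.label
            if c.parents:
                rec["parents"] = sorted(c.parents)
            if c.disjoint_with:
                rec["disjoint_with"] = sorted(c.disjoint_with)
            if c.source != "native":
                rec["source"] = c.source
            if c.iri:
                rec["iri"] = c.iri
            classes.append(rec)
        props = []
        for pid in sorted(self.properties):
            p = self.properties[pid]
            rec = {"id": p.id}
            if p.super_property:
                rec["super"] = p.super_property
            if p.inverse:
                rec["inverse"] = p.inverse
            if p.domain:
                rec["domain"] = p.domain
            if p.range:
                rec["range"] = p.range
            if p.asserted:
                rec["asserted"] = True
            props.append(rec)
        axioms = []
        for ax in self.defined_classes:
            axioms.append({
                "class": ax.class_id,
                "direction": ax.direction,
                "condition": [
                    {"property": pr, "filler": f, "quantifier": q, "cardinality": n}
                    for pr, f, q, n in ax.condition
                ],
            })
        out = {"namespace": self.namespace, "classes": classes,
               "properties": props}
        if axioms:
            out["defined_classes"] = axioms
        return out

    def serialize(self) -> str:
        return yaml.safe_dump(self.to_config_dict(), sort_keys=False,
                              allow_unicode=True)


def _as_tuple(value) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return (value,)
    return tuple(value)


def schema_from_dict(cfg: Mapping) -> Schema:
    classes = []
    for rec in cfg.get("classes", []):
        try:
            cid = rec["id"]
        except (TypeError, KeyError):
            raise SchemaError(f"class record without id: {rec!r}")
        classes.append(SchemaClass(
            id=cid,
            label=rec.get("label", ""),
            parents=_as_tuple(rec.get("parents")),
            disjoint_with=_as_tuple(rec.get("disjoint_with")),
            source=rec.get("source", "native"),
            iri=rec.get("iri"),
        ))
    props = []
    for rec in cfg.get("properties", []):
        props.append(PropertyDef(
            id=rec["id"],
            super_property=rec.get("super"),
            inverse=rec.get("inverse"),
            domain=rec.get("domain"),
            range=rec.get("range"),
            asserted=bool(rec.get("asserted", False)),
        ))
    axioms = []
    for rec in cfg.get("defined_classes", []):
        cond = tuple(
            (c["property"], c["filler"], c.get("quantifier", "min"),
             int(c.get("cardinality", 1)))
            for c in rec.get("condition", [])
        )
        axioms.append(DefinedClassAxiom(
            class_id=rec["class"], condition=cond,
            direction=rec.get("direction", "necessary"),
        ))
    return Schema(classes, props, axioms,
                  namespace=cfg.get("namespace", DEFAULT_NAMESPACE))


def build_core_schema(schema_config: str | Path | io.TextIOBase | None = None) -> Schema:
    """Load a schema config; with no argument, load the shipped core schema."""
    if schema_config is None:
        schema_config = core_schema_path()
    if isinstance(schema_config, (str, Path)):
        with open(schema_config, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(schema_config)
    if not isinstance(cfg, Mapping):
        raise SchemaError("schema config must be a mapping")
    return schema_from_dict(cfg)


def core_schema_path() -> Path:
    return Path(__file__).parent / "data" / "core_schema.yaml"
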