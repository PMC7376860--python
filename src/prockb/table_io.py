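"""Instantiation-table loading and ontology/report export.

The canonical table dialect is a CSV/TSV with header
``subject,kind,predicate,object``; each non-comment row is exactly one
declared assertion:

* ``kind=type``: ``predicate`` is a class id, ``object`` empty — a declared
  class assertion;
* ``kind=property``: ``predicate`` is a property id, ``object`` an
  individual id — a declared property assertion.

Individuals are registered on first mention.  Identifiers are
whitespace-trimmed but otherwise taken verbatim (case-sensitive, internal
spaces preserved: biological labels such as "Phosphoglycerate kinase 1"
are ids).  Published spreadsheet layouts reshape mechanically into this
two-shape dialect.

RDF export writes the schema (subclass / disjointness / inverse triples)
and the instance layer; the provenance-preserving format is TriG with two
named graphs (``:declared`` and ``:inferred``), plain Turtle flattens the
distinction.  Imported classes keep their original GO/ChEBI IRIs verbatim.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdflib import Dataset, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .errors import TableFormatError, UsageError
from .kb import DECLARED, INFERRED, KnowledgeBase
from .schema import Schema

HEADER = ("subject", "kind", "predicate", "object")


@dataclass(frozen=True)
class InstantiationRow:
    subject: str
    kind: str  # "type" | "property"
    predicate: str
    object: str = ""


@dataclass
class LoadReport:
    """Row-level diagnostics collected while loading a table."""

    rows: int = 0
    class_assertions: int = 0
    property_assertions: int = 0
    warnings: list[str] = field(default_factory=list)


def _sniff_delimiter(sample: str) -> str:
    header = sample.splitlines()[0] if sample else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header \
        else ","


def parse_rows(text: str, path: str = "<string>") -> list[tuple[int, InstantiationRow]]:
    lines = text.splitlines()
    if not lines:
        return []
    delim = _sniff_delimiter(text)
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows: list[tuple[int, InstantiationRow]] = []
    header: Optional[list[str]] = None
    for lineno, rec in enumerate(reader, start=1):
        if not rec or all(not c.strip() for c in rec):
            continue
        if rec[0].lstrip().startswith("#"):
            continue
        cells = [c.strip() for c in rec]
        if header is None:
            header = [c.lower() for c in cells]
            if header[:4] != list(HEADER):
                raise TableFormatError(
                    f"unexpected header {cells[:4]!r}; expected "
                    f"{','.join(HEADER)}", line=lineno, path=path)
            continue
        cells += [""] * (4 - len(cells))
        rows.append((lineno, InstantiationRow(
            subject=cells[0], kind=cells[1].lower(), predicate=cells[2],
            object=cells[3])))
    return rows


def load_instantiation_table(path_or_text: str | Path, schema: Schema,
                             strict: bool = False,
                             report: Optional[LoadReport] = None
                             ) -> KnowledgeBase:
    """Read a table into a fresh knowledge base (all assertions declared).

    ``strict=True`` turns recoverable diagnostics (non-assertable property
    used, duplicate row) into errors; otherwise they are warnings collected
    in ``report`` (and emitted via :mod:`warnings`).
    """
    if isinstance(path_or_text, Path) or (
            isinstance(path_or_text, str) and "\n" not in path_or_text
            and Path(path_or_text).exists()):
        path = str(path_or_text)
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        path = "<string>"
        text = str(path_or_text)
    kb = KnowledgeBase(schema)
    rep = report if report is not None else LoadReport()

    def diag(msg: str, lineno: int) -> None:
        full = f"{path}:{lineno}: {msg}"
        if strict:
            raise TableFormatError(msg, line=lineno, path=path)
        rep.warnings.append(full)
        warnings.warn(full, stacklevel=2)

    assertable = set(schema.assertable_properties())
    for lineno, row in parse_rows(text, path):
        rep.rows += 1
        if not row.subject:
            raise TableFormatError("empty subject", line=lineno, path=path)
        if row.kind == "type":
            if row.predicate not in schema:
                raise TableFormatError(
                    f"unknown class {row.predicate!r}", line=lineno, path=path)
            if row.object:
                raise TableFormatError(
                    "type row must have an empty object column",
                    line=lineno, path=path)
            if kb.has_class_assertion(row.subject, row.predicate):
                diag(f"duplicate type row ({row.subject!r}, {row.predicate!r})",
                     lineno)
                continue
            kb.assert_class(row.subject, row.predicate, DECLARED, "input")
            rep.class_assertions += 1
        elif row.kind == "property":
            if not schema.has_property(row.predicate):
                raise TableFormatError(
                    f"unknown property {row.predicate!r}", line=lineno,
                    path=path)
            if not row.object:
                raise TableFormatError(
                    "property row needs an object column", line=lineno,
                    path=path)
            if row.predicate not in assertable:
                diag(f"property {row.predicate!r} is not user-assertable",
                     lineno)
            if kb.has_property_assertion(row.subject, row.predicate, row.object):
                diag(f"duplicate property row ({row.subject!r}, "
                     f"{row.predicate!r}, {row.object!r})", lineno)
                continue
            kb.assert_property(row.subject, row.predicate, row.object,
                               DECLARED, "input")
            rep.property_assertions += 1
        else:
            raise TableFormatError(
                f"unknown statement kind {row.kind!r} (expected type|property)",
                line=lineno, path=path)
    return kb


def export_table(kb: KnowledgeBase, path: Optional[str | Path] = None) -> str:
    """Write the *declared* assertions back to the canonical CSV dialect."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(HEADER)
    for a in sorted((a for a in kb.class_assertions() if a.status == DECLARED),
                    key=lambda a: a.key):
        writer.writerow([a.individual, "type", a.class_id, ""])
    for a in sorted((a for a in kb.property_assertions()
                     if a.status == DECLARED), key=lambda a: a.key):
        writer.writerow([a.subject, "property", a.property_id, a.object])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# -- RDF export --------------------------------------------------------------


def _class_ref(schema: Schema, ns: Namespace, class_id: str) -> URIRef:
    c = schema.classes[class_id]
    if c.iri:
        return URIRef(c.iri)
    return ns[class_id.replace(" ", "_")]


def _prop_ref(ns: Namespace, prop_id: str) -> URIRef:
    return ns[prop_id]


def _ind_ref(ns: Namespace, ind_id: str) -> URIRef:
    from urllib.parse import quote
    return ns["ind/" + quote(ind_id, safe="")]


def schema_to_graph(schema: Schema, graph: Optional[Graph] = None) -> Graph:
    """Terminological layer as subclass/disjointness/inverse triples."""
    g = graph if graph is not None else Graph()
    ns = Namespace(schema.namespace)
    g.bind("kb", ns)
    g.bind("owl", OWL)
    for c in schema.classes.values():
        ref = _class_ref(schema, ns, c.id)
        g.add((ref, RDF.type, OWL.Class))
        if c.label:
            g.add((ref, RDFS.label, Literal(c.label)))
        for p in c.parents:
            g.add((ref, RDFS.subClassOf, _class_ref(schema, ns, p)))
        for d in c.disjoint_with:
            g.add((ref, OWL.disjointWith, _class_ref(schema, ns, d)))
    for p in schema.properties.values():
        ref = _prop_ref(ns, p.id)
        g.add((ref, RDF.type, OWL.ObjectProperty))
        if p.super_property:
            g.add((ref, RDFS.subPropertyOf, _prop_ref(ns, p.super_property)))
        if p.inverse:
            g.add((ref, OWL.inverseOf, _prop_ref(ns, p.inverse)))
        if p.domain:
            g.add((ref, RDFS.domain, _class_ref(schema, ns, p.domain)))
        if p.range:
            g.add((ref, RDFS.range, _class_ref(schema, ns, p.range)))
    return g


def export_ontology(kb: KnowledgeBase, path: str | Path,
                    format: str = "trig") -> None:
    """Serialise schema + instance layer.

    ``trig`` (default) keeps declared and inferred assertions in two named
    graphs so provenance survives a round trip; ``turtle`` / ``xml``
    flatten everything into one graph.
    """
    schema = kb.schema
    ns = Namespace(schema.namespace)
    if format == "trig":
        ds = Dataset()
        ds.bind("kb", ns)
        ds.bind("owl", OWL)
        schema_to_graph(schema, ds.graph(ns["schema"]))
        declared = ds.graph(ns["declared"])
        inferred = ds.graph(ns["inferred"])
        for a in kb.class_assertions():
            g = declared if a.status == DECLARED else inferred
            g.add((_ind_ref(ns, a.individual), RDF.type,
                   _class_ref(schema, ns, a.class_id)))
        for a in kb.property_assertions():
            g = declared if a.status == DECLARED else inferred
            g.add((_ind_ref(ns, a.subject), _prop_ref(ns, a.property_id),
                   _ind_ref(ns, a.object)))
        for ind in kb.individuals.values():
            declared.add((_ind_ref(ns, ind.id), RDF.type, OWL.NamedIndividual))
            declared.add((_ind_ref(ns, ind.id), RDFS.label, Literal(ind.id)))
        ds.serialize(destination=str(path), format="trig")
        return
    if format in ("turtle", "ttl", "xml", "pretty-xml"):
        g = schema_to_graph(schema)
        ns = Namespace(schema.namespace)
        for a in kb.class_assertions():
            g.add((_ind_ref(ns, a.individual), RDF.type,
                   _class_ref(schema, ns, a.class_id)))
        for a in kb.property_assertions():
            g.add((_ind_ref(ns, a.subject), _prop_ref(ns, a.property_id),
                   _ind_ref(ns, a.object)))
        for ind in kb.individuals.values():
            g.add((_ind_ref(ns, ind.id), RDF.type, OWL.NamedIndividual))
            g.add((_ind_ref(ns, ind.id), RDFS.label, Literal(ind.id)))
        fmt = "turtle" if format == "ttl" else format
        g.serialize(destination=str(path), format=fmt)
        return
    raise UsageError(f"unsupported export format {format!r}")


def load_ontology(path: str | Path, schema: Schema) -> KnowledgeBase:
    """Re-read a TriG export into a knowledge base (inverse of export)."""
    from urllib.parse import unquote
    ds = Dataset()
    ds.parse(str(path), format="trig")
    ns = str(schema.namespace)
    iri2cls = {}
    for c in schema.classes.values():
        iri2cls[str(_class_ref(schema, Namespace(ns), c.id))] = c.id
    kb = KnowledgeBase(schema)

    def ind_id(ref) -> Optional[str]:
        s = str(ref)
        if s.startswith(ns + "ind/"):
            return unquote(s[len(ns) + 4:])
        return None

    for graph_name, status in ((ns + "declared", DECLARED),
                               (ns + "inferred", INFERRED)):
        g = ds.graph(URIRef(graph_name))
        for s, p, o in g:
            si = ind_id(s)
            if si is None:
                continue
            if p == RDF.type:
                cid = iri2cls.get(str(o))
                if cid is not None:
                    kb.assert_class(si, cid, status, "import")
                continue
            if p == RDFS.label:
                kb.add_individual(si, str(o))
                continue
            pid = str(p)[len(ns):] if str(p).startswith(ns) else None
            oi = ind_id(o)
            if pid and oi is not None and schema.has_property(pid):
                kb.assert_property(si, pid, oi, status, "import")
    return kb


# -- diff --------------------------------------------------------------------


@dataclass
class DiffEntry:
    kind: str
    key: tuple
    status: str
    provenance: str

    def __str__(self):
        if self.kind == "class":
            body = f"{self.key[0]} a {self.key[1]}"
        else:
            body = f"{self.key[0]} {self.key[1]} {self.key[2]}"
        return f"[{self.status}/{self.provenance}] {body}"


@dataclass
class DiffReport:
    only_a: list[DiffEntry] = field(default_factory=list)
    only_b: list[DiffEntry] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.only_a and not self.only_b

    def provenances(self) -> set[str]:
        return {e.provenance for e in self.only_a + self.only_b}

    def to_text(self) -> str:
        lines = []
        for tag, entries in (("only in A", self.only_a),
                             ("only in B", self.only_b)):
            lines.append(f"# {tag}: {len(entries)}")
            lines.extend(f"  {e}" for e in entries)
        return "\n".join(lines) + "\n"


def diff_kb(kb_a: KnowledgeBase, kb_b: KnowledgeBase) -> DiffReport:
    """Symmetric difference of two stores over the same schema."""
    if kb_a.schema is not kb_b.schema and \
            kb_a.schema.to_config_dict() != kb_b.schema.to_config_dict():
        raise UsageError("cannot diff knowledge bases over different schemas")
    report = DiffReport()

    def entries(kb, keys, kind):
        out = []
        for k in sorted(keys):
            a = (kb.get_class_assertion(*k) if kind == "class"
                 else kb.get_property_assertion(*k))
            out.append(DiffEntry(kind, k, a.status, a.provenance))
        return out

    ca = set(a.key for a in kb_a.class_assertions())
    cb = set(a.key for a in kb_b.class_assertions())
    pa = set(a.key for a in kb_a.property_assertions())
    pb = set(a.key for a in kb_b.property_assertions())
    report.only_a = entries(kb_a, ca - cb, "class") + entries(kb_a, pa - pb, "prop")
    report.only_b = entries(kb_b, cb - ca, "class") + entries(kb_b, pb - pa, "prop")
    return report
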