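"""Instance layer: individuals, class/property assertions, metrics.

Every assertion carries a ``declared``/``inferred`` status and a provenance
tag (``"input"`` for table-loaded assertions, a rule id or entailment name
for reasoner-derived ones).  A (subject, predicate[, object]) pair is stored
at most once; a declared assertion is never demoted to inferred.

Distinct individual ids denote distinct individuals (unique-name
assumption): the rule builtin ``DifferentFrom`` evaluates as id inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import ConsistencyError, KBLookupError, UsageError
from .schema import Schema

DECLARED = "declared"
INFERRED = "inferred"


@dataclass
class Individual:
    id: str
    label: Optional[str] = None


@dataclass(frozen=True)
class ClassAssertion:
    individual: str
    class_id: str
    status: str
    provenance: str

    @property
    def key(self):
        return (self.individual, self.class_id)


@dataclass(frozen=True)
class PropertyAssertion:
    subject: str
    property_id: str
    object: str
    status: str
    provenance: str

    @property
    def key(self):
        return (self.subject, self.property_id, self.object)


@dataclass
class MetricsReport:
    """Declared/inferred assertion counts and typing coverage."""

    individuals: int = 0
    declared_class_assertions: int = 0
    declared_property_assertions: int = 0
    inferred_class_assertions: int = 0
    inferred_property_assertions: int = 0
    typed_individuals: int = 0

    @property
    def typing_coverage(self) -> float:
        """Fraction of individuals carrying at least one class."""
        if self.individuals == 0:
            return 0.0
        return self.typed_individuals / self.individuals

    def to_dict(self) -> dict:
        return {
            "individuals": self.individuals,
            "declared_class_assertions": self.declared_class_assertions,
            "declared_property_assertions": self.declared_property_assertions,
            "inferred_class_assertions": self.inferred_class_assertions,
            "inferred_property_assertions": self.inferred_property_assertions,
            "typed_individuals": self.typed_individuals,
            "typing_coverage": self.typing_coverage,
        }

    def to_text(self) -> str:
        lines = [f"{k}: {v}" for k, v in self.to_dict().items()]
        return "\n".join(lines) + "\n"


class KnowledgeBase:
    """Schema + individual registry + assertion store with indexes.

    Single-wildcard queries are served from hash indexes (class -> members,
    (property, subject) -> objects, (property, object) -> subjects) so rule
    matching stays sublinear in store size.
    """

    def __init__(self, schema: Schema):
        self.schema = schema
        self.individuals: dict[str, Individual] = {}
        self._class_assertions: dict[tuple[str, str], ClassAssertion] = {}
        self._prop_assertions: dict[tuple[str, str, str], PropertyAssertion] = {}
        # indexes
        self._cls2inds: dict[str, set[str]] = {}
        self._ind2cls: dict[str, set[str]] = {}
        self._p_so: dict[str, dict[str, set[str]]] = {}
        self._p_os: dict[str, dict[str, set[str]]] = {}

    # -- registry -----------------------------------------------------------

    def add_individual(self, ind_id: str, label: Optional[str] = None) -> Individual:
        ind = self.individuals.get(ind_id)
        if ind is None:
            ind = Individual(ind_id, label)
            self.individuals[ind_id] = ind
        elif label and not ind.label:
            ind.label = label
        return ind

    def has_individual(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    # -- assertions ---------------------------------------------------------

    def assert_class(self, individual: str, class_id: str,
                     status: str = DECLARED, provenance: str = "input",
                     auto_register: bool = True) -> bool:
        """Add a class assertion; returns True iff the pair was new.

        Idempotent; a later declared assertion upgrades an inferred one.
        Raises :class:`ConsistencyError` when the individual would carry two
        disjoint classes.
        """
        if class_id not in self.schema:
            raise KBLookupError(f"unknown class {class_id!r}")
        if individual not in self.individuals:
            if not auto_register:
                raise KBLookupError(f"unknown individual {individual!r}")
            self.add_individual(individual)
        key = (individual, class_id)
        existing = self._class_assertions.get(key)
        if existing is not None:
            if existing.status == INFERRED and status == DECLARED:
                self._class_assertions[key] = ClassAssertion(
                    individual, class_id, DECLARED, provenance)
            return False
        # disjointness guard against every class already carried
        for other in self._ind2cls.get(individual, ()):
            if self.schema.are_disjoint(class_id, other):
                prev = self._class_assertions[(individual, other)]
                raise ConsistencyError(individual, class_id, other,
                                       provenance, prev.provenance)
        self._class_assertions[key] = ClassAssertion(
            individual, class_id, status, provenance)
        self._cls2inds.setdefault(class_id, set()).add(individual)
        self._ind2cls.setdefault(individual, set()).add(class_id)
        return True

    def assert_property(self, subject: str, property_id: str, object: str,
                        status: str = DECLARED, provenance: str = "input",
                        auto_register: bool = True) -> bool:
        """Add a property assertion; returns True iff the triple was new."""
        if not self.schema.has_property(property_id):
            raise KBLookupError(f"unknown property {property_id!r}")
        for ind in (subject, object):
            if ind not in self.individuals:
                if not auto_register:
                    raise KBLookupError(f"unknown individual {ind!r}")
                self.add_individual(ind)
        key = (subject, property_id, object)
        existing = self._prop_assertions.get(key)
        if existing is not None:
            if existing.status == INFERRED and status == DECLARED:
                self._prop_assertions[key] = PropertyAssertion(
                    subject, property_id, object, DECLARED, provenance)
            return False
        self._prop_assertions[key] = PropertyAssertion(
            subject, property_id, object, status, provenance)
        self._p_so.setdefault(property_id, {}).setdefault(subject, set()).add(object)
        self._p_os.setdefault(property_id, {}).setdefault(object, set()).add(subject)
        return True

    # -- accessors ----------------------------------------------------------

    def class_assertions(self) -> Iterator[ClassAssertion]:
        return iter(self._class_assertions.values())

    def property_assertions(self) -> Iterator[PropertyAssertion]:
        return iter(self._prop_assertions.values())

    def classes_of(self, individual: str) -> frozenset[str]:
        return frozenset(self._ind2cls.get(individual, frozenset()))

    def members_of(self, class_id: str) -> frozenset[str]:
        return frozenset(self._cls2inds.get(class_id, frozenset()))

    def objects(self, subject: str, property_id: str) -> frozenset[str]:
        return frozenset(self._p_so.get(property_id, {}).get(subject, frozenset()))

    def subjects(self, property_id: str, object: str) -> frozenset[str]:
        return frozenset(self._p_os.get(property_id, {}).get(object, frozenset()))

    def has_class_assertion(self, individual: str, class_id: str) -> bool:
        return (individual, class_id) in self._class_assertions

    def has_property_assertion(self, subject: str, property_id: str,
                               object: str) -> bool:
        return (subject, property_id, object) in self._prop_assertions

    def get_class_assertion(self, individual, class_id):
        return self._class_assertions.get((individual, class_id))

    def get_property_assertion(self, subject, property_id, object):
        return self._prop_assertions.get((subject, property_id, object))

    # -- pattern query -------------------------------------------------------

    def query(self, subject=None, property=None, object=None,
              individual=None, class_id=None):
        """Match a triple pattern or an (individual, class) pattern.

        Pass ``subject``/``property``/``object`` (any of them ``None`` as a
        wildcard) for property assertions, or ``individual``/``class_id``
        for class assertions.  Mixing the two shapes is a usage error.
        """
        triple_args = (subject, property, object)
        class_args = (individual, class_id)
        if any(a is not None for a in triple_args) and \
           any(a is not None for a in class_args):
            raise UsageError("mix of triple and class-assertion pattern")
        if any(a is not None for a in class_args):
            return self._query_class(individual, class_id)
        return self._query_triple(subject, property, object)

    def _query_class(self, individual, class_id):
        if individual is not None and class_id is not None:
            a = self._class_assertions.get((individual, class_id))
            return [a] if a else []
        if individual is not None:
            return sorted((self._class_assertions[(individual, c)]
                           for c in self._ind2cls.get(individual, ())),
                          key=lambda a: a.class_id)
        if class_id is not None:
            return sorted((self._class_assertions[(i, class_id)]
                           for i in self._cls2inds.get(class_id, ())),
                          key=lambda a: a.individual)
        return sorted(self._class_assertions.values(), key=lambda a: a.key)

    def _query_triple(self, subject, property, object):
        if property is not None and not self.schema.has_property(property):
            raise KBLookupError(f"unknown property {property!r}")
        if property is not None:
            if subject is not None:
                objs = self._p_so.get(property, {}).get(subject, ())
                cands = [(subject, property, o) for o in objs]
            elif object is not None:
                subs = self._p_os.get(property, {}).get(object, ())
                cands = [(s, property, object) for s in subs]
            else:
                cands = [k for k in self._prop_assertions
                         if k[1] == property]
        else:
            cands = list(self._prop_assertions)
            if subject is not None:
                cands = [k for k in cands if k[0] == subject]
            if object is not None:
                cands = [k for k in cands if k[2] == object]
        out = [self._prop_assertions[k] for k in cands
               if (object is None or k[2] == object)]
        return sorted(out, key=lambda a: a.key)

    # -- metrics ------------------------------------------------------------

    def metrics(self, exclude_roots: bool = False) -> MetricsReport:
        """Count declared/inferred assertions and typing coverage.

        ``exclude_roots=True`` drops membership in the hierarchy roots from
        the inferred class-assertion count (a counting convention switch;
        some ontology tools do not report top-level membership).
        """
        roots = set(self.schema.roots()) if exclude_roots else set()
        dc = ic = 0
        for a in self._class_assertions.values():
            if a.status == DECLARED:
                dc += 1
            elif a.class_id not in roots:
                ic += 1
        dp = sum(1 for a in self._prop_assertions.values()
                 if a.status == DECLARED)
        ip = len(self._prop_assertions) - dp
        return MetricsReport(
            individuals=len(self.individuals),
            declared_class_assertions=dc,
            declared_property_assertions=dp,
            inferred_class_assertions=ic,
            inferred_property_assertions=ip,
            typed_individuals=sum(1 for i in self.individuals
                                  if self._ind2cls.get(i)),
        )

    # -- misc ---------------------------------------------------------------

    def copy(self) -> "KnowledgeBase":
        clone = KnowledgeBase(self.schema)
        for ind in self.individuals.values():
            clone.add_individual(ind.id, ind.label)
        clone._class_assertions = dict(self._class_assertions)
        clone._prop_assertions = dict(self._prop_assertions)
        clone._cls2inds = {k: set(v) for k, v in self._cls2inds.items()}
        clone._ind2cls = {k: set(v) for k, v in self._ind2cls.items()}
        clone._p_so = {p: {s: set(o) for s, o in d.items()}
                       for p, d in self._p_so.items()}
        clone._p_os = {p: {o: set(s) for o, s in d.items()}
                       for p, d in self._p_os.items()}
        return clone

    def assertion_keys(self):
        """All assertion keys as a set (class pairs and property triples)."""
        keys = {("class",) + k for k in self._class_assertions}
        keys |= {("prop",) + k for k in self._prop_assertions}
        return keys

    def __len__(self):
        return len(self._class_assertions) + len(self._prop_assertions)
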