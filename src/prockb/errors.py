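"""Exception hierarchy for prockb.

All errors raised by the library derive from :class:`ProckbError` so callers
(and the CLI) can catch one base class.
"""


class ProckbError(Exception):
    """Base class for all prockb errors."""


class SchemaError(ProckbError):
    """Schema config could not be loaded or is structurally invalid."""


class SchemaCycleError(SchemaError):
    """The subclass graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "subclass hierarchy contains a cycle: " + " -> ".join(self.cycle)
        )


class UnresolvedReferenceError(SchemaError):
    """A class/property reference does not resolve to a declared entity."""

    def __init__(self, ref, context=""):
        self.ref = ref
        msg = f"unresolved reference {ref!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class KBLookupError(ProckbError, KeyError):
    """An individual, class or property id is unknown to the knowledge base."""


class ConsistencyError(ProckbError):
    """An individual was asserted to belong to two disjoint classes."""

    def __init__(self, individual, class_a, class_b, provenance_a=None,
                 provenance_b=None):
        self.individual = individual
        self.class_a = class_a
        self.class_b = class_b
        self.provenance_a = provenance_a
        self.provenance_b = provenance_b
        detail = ""
        if provenance_a or provenance_b:
            detail = (f" (derived via {provenance_a or '?'} and "
                      f"{provenance_b or '?'})")
        super().__init__(
            f"individual {individual!r} typed by disjoint classes "
            f"{class_a!r} and {class_b!r}{detail}"
        )


class RuleDefinitionError(ProckbError):
    """A rule is malformed (unsafe head variable, unknown atom kind, ...)."""


class TableFormatError(ProckbError):
    """An instantiation table row could not be interpreted."""

    def __init__(self, message, line=None, path=None):
        self.line = line
        self.path = path
        loc = ""
        if path is not None:
            loc += str(path)
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class StructuralError(ProckbError):
    """A pathway's precedes ordering is not a chain (cycle or branching)."""


class GenerationError(ProckbError):
    """Synthetic-network parameters are infeasible."""


class UsageError(ProckbError):
    """A query pattern or operation was invoked with malformed arguments."""
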