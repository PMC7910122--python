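"""Exception hierarchy shared across the engine.

Every subsystem raises from this tree so callers can catch
:class:`EpichartError` at an interface boundary (e.g. the CLI) and map
specific subclasses to protocol behaviour (e.g. HL7 validation failures
are acknowledged with an AE rather than propagated).
"""

from __future__ import annotations


class EpichartError(Exception):
    """Base class for all engine errors."""


# --- HL7 ---------------------------------------------------------------


class Hl7Error(EpichartError):
    """Base class for HL7 parsing/construction errors."""


class Hl7StructuralError(Hl7Error):
    """Message text violates basic HL7 v2 structure (no MSH, empty, ...)."""


class Hl7EncodingError(Hl7Error):
    """Encoding characters in MSH-1/MSH-2 are inconsistent or invalid."""


class UnsupportedMessageTypeError(Hl7Error):
    """MSH-9 names a message type the engine does not handle."""


class UnsupportedVersionError(Hl7Error):
    """MSH-12 names an HL7 version other than 2.3."""


# --- Validation / state ------------------------------------------------


class ValidationError(EpichartError):
    """Input fails a semantic validation contract.

    ``details`` lists the offending items (missing attributes, bad term
    ids, ...) so callers can surface them all at once.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        super().__init__(message)
        self.details = details or []


class StateError(EpichartError):
    """Operation applied to an object in the wrong lifecycle state."""


class PermissionError_(EpichartError):
    """Actor's roles do not grant the attempted action."""


class PolicyError(EpichartError):
    """Policy lookup used an unknown action or resource name."""


class DuplicateOrderError(EpichartError):
    """An order with this placer id was already ingested."""


class MappingError(EpichartError):
    """Order's procedure code does not map to a registered report type."""


# --- Ontology ----------------------------------------------------------


class OntologyError(EpichartError):
    """Base class for ontology load/lookup errors."""


class CycleError(OntologyError):
    """Parent links contain a cycle; the offending term ids are attached."""

    def __init__(self, cycle: list[str]):
        super().__init__(f"cycle in parent links: {' -> '.join(cycle)}")
        self.cycle = cycle


class DanglingParentError(OntologyError):
    """A term references a parent id that does not exist."""


class DuplicateTermError(OntologyError):
    """Two rows share one term id."""


class UnknownTermError(OntologyError):
    """Lookup of a term id not present in the ontology."""


# --- Scheduling --------------------------------------------------------


class CoverageError(EpichartError):
    """Schedule has no assignment for the requested date/service line."""


class ConsistencyError(EpichartError):
    """Operation would violate a structural invariant (e.g. double-booking)."""
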