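"""In-memory representation of HL7 v2.3 messages.

A message is an ordered list of segments; a segment is a 3-letter id
plus a 1-based list of field values. Field values are kept as the raw
pipe-free strings from the wire (repetitions ``~``, components ``^`` and
subcomponents ``&`` intact), so serialization can reproduce input
byte-for-byte; accessors split on demand.

MSH is special-cased per the standard: MSH-1 is the field separator
character itself and MSH-2 the four encoding characters, so the text
``MSH|^~\\&|APP`` has MSH-1 ``|``, MSH-2 ``^~\\&`` and MSH-3 ``APP``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from epichart.errors import Hl7StructuralError

FIELD_SEP = "|"
COMPONENT_SEP = "^"
REPETITION_SEP = "~"
ESCAPE_CHAR = "\\"
SUBCOMPONENT_SEP = "&"
ENCODING_CHARS = "^~\\&"
SEGMENT_SEP = "\r"

SUPPORTED_VERSION = "2.3"
SUPPORTED_MESSAGE_TYPES = frozenset({"ORM^O01", "ORU^R01", "DFT^P03", "ACK"})

_UNESCAPES = {"F": FIELD_SEP, "S": COMPONENT_SEP, "T": SUBCOMPONENT_SEP,
              "R": REPETITION_SEP, "E": ESCAPE_CHAR}


def escape_text(value: str) -> str:
    """Escape HL7 delimiter characters in free text for safe embedding."""
    out = value.replace(ESCAPE_CHAR, "\\E\\")  # escape char first
    out = out.replace(FIELD_SEP, "\\F\\")
    out = out.replace(COMPONENT_SEP, "\\S\\")
    out = out.replace(SUBCOMPONENT_SEP, "\\T\\")
    out = out.replace(REPETITION_SEP, "\\R\\")
    return out


def unescape_text(value: str) -> str:
    """Invert :func:`escape_text` (``\\F\\`` → ``|`` and so on)."""
    def sub(m: re.Match[str]) -> str:
        return _UNESCAPES.get(m.group(1), m.group(0))

    return re.sub(r"\\([FSTRE])\\", sub, value)


@dataclass
class Segment:
    """One HL7 segment: 3-character id plus raw field values.

    ``fields[0]`` is field 1; :meth:`get` uses HL7's 1-based convention.
    """

    segment_id: str
    fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.segment_id) != 3 or not self.segment_id.isalnum():
            raise Hl7StructuralError(
                f"segment id must be 3 alphanumeric characters, got {self.segment_id!r}"
            )

    def get(self, index: int) -> str:
        """Raw value of field ``index`` (1-based); '' if absent."""
        if index < 1:
            raise IndexError("HL7 fields are 1-based")
        if index > len(self.fields):
            return ""
        return self.fields[index - 1]

    def set(self, index: int, value: str) -> None:
        if index < 1:
            raise IndexError("HL7 fields are 1-based")
        while len(self.fields) < index:
            self.fields.append("")
        self.fields[index - 1] = value

    def repetitions(self, index: int) -> list[str]:
        raw = self.get(index)
        return raw.split(REPETITION_SEP) if raw else []

    def component(self, index: int, component: int, repetition: int = 1) -> str:
        """Component ``component`` (1-based) of a field, '' if absent."""
        reps = self.repetitions(index)
        if repetition > len(reps):
            return ""
        parts = reps[repetition - 1].split(COMPONENT_SEP)
        if component > len(parts):
            return ""
        return parts[component - 1]


@dataclass
class Hl7Message:
    """A parsed HL7 v2.3 message: MSH header plus ordered segments."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise Hl7StructuralError("message has no segments")
        if self.segments[0].segment_id != "MSH":
            raise Hl7StructuralError("first segment must be MSH")

    @property
    def msh(self) -> Segment:
        return self.segments[0]

    # MSH fields use HL7 numbering: MSH-1 is the field separator.
    @property
    def field_separator(self) -> str:
        return self.msh.get(1)

    @property
    def encoding_characters(self) -> str:
        return self.msh.get(2)

    @property
    def sending_app(self) -> str:
        return self.msh.get(3)

    @property
    def sending_facility(self) -> str:
        return self.msh.get(4)

    @property
    def receiving_app(self) -> str:
        return self.msh.get(5)

    @property
    def receiving_facility(self) -> str:
        return self.msh.get(6)

    @property
    def timestamp(self) -> str:
        return self.msh.get(7)

    @property
    def message_type(self) -> str:
        return self.msh.get(9)

    @property
    def control_id(self) -> str:
        return self.msh.get(10)

    @property
    def version(self) -> str:
        return self.msh.get(12)

    def segment(self, segment_id: str) -> Segment:
        """First segment with the given id; structural error if absent."""
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise Hl7StructuralError(f"message has no {segment_id} segment")

    def all_segments(self, segment_id: str) -> list[Segment]:
        return [s for s in self.segments if s.segment_id == segment_id]

    def has_segment(self, segment_id: str) -> bool:
        return any(s.segment_id == segment_id for s in self.segments)
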