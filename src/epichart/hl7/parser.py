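"""HL7 v2.3 wire-format reader and writer.

Segments are separated by carriage returns on the wire (newlines are
accepted on read), fields by ``|``, with the standard encoding
characters ``^~\\&`` unless MSH-2 overrides them. Serialization emits
the canonical form: ``\\r``-separated segments with trailing empty
fields trimmed, so ``serialize(parse(text)) == text`` for canonical
input.
"""

from __future__ import annotations

from epichart.errors import (
    Hl7EncodingError,
    Hl7StructuralError,
    UnsupportedMessageTypeError,
    UnsupportedVersionError,
)
from epichart.hl7.model import (
    SEGMENT_SEP,
    SUPPORTED_MESSAGE_TYPES,
    SUPPORTED_VERSION,
    Hl7Message,
    Segment,
)

MLLP_START = "\x0b"
MLLP_END = "\x1c\x0d"


def parse_message(raw: str, profile=None) -> Hl7Message:
    """Parse raw HL7 v2.3 text into a structured message.

    Parameters
    ----------
    raw
        Pipe-delimited message text beginning with ``MSH``. Segment
        separators may be ``\\r``, ``\\n`` or ``\\r\\n``; optional
        MLLP framing bytes are stripped.
    profile
        Optional :class:`~epichart.hl7.dialect.DialectProfile`; when
        given, the sending facility is checked against the profile's
        expected facility codes.

    Raises
    ------
    Hl7StructuralError
        If the text does not begin with an MSH segment.
    Hl7EncodingError
        If MSH-1/MSH-2 are malformed.
    UnsupportedMessageTypeError
        If MSH-9 is not one of ORM^O01, ORU^R01, DFT^P03 or ACK.
    UnsupportedVersionError
        If MSH-12 names a version other than 2.3.
    """
    text = raw.strip("\x0b\x1c\x0d\n ")
    if not text.startswith("MSH"):
        raise Hl7StructuralError("message must begin with an MSH segment")
    if len(text) < 9:
        raise Hl7StructuralError("MSH segment truncated")

    field_sep = text[3]
    if field_sep.isalnum() or field_sep.isspace():
        raise Hl7EncodingError(f"invalid field separator {field_sep!r}")
    lines = [ln for ln in text.replace("\r\n", "\r").replace("\n", "\r").split("\r") if ln]

    segments: list[Segment] = []
    for i, line in enumerate(lines):
        seg_id, _, rest = line.partition(field_sep)
        if i == 0:
            # MSH-1 is the separator itself; MSH-2 the encoding characters.
            tokens = rest.split(field_sep)
            encoding = tokens[0]
            if len(encoding) != 4:
                raise Hl7EncodingError(
                    f"MSH-2 must hold exactly 4 encoding characters, got {encoding!r}"
                )
            if len(set(encoding) | {field_sep}) != 5:
                raise Hl7EncodingError("encoding characters must be distinct")
            segments.append(Segment("MSH", [field_sep] + tokens))
        else:
            if len(seg_id) != 3:
                raise Hl7StructuralError(f"malformed segment line {line!r}")
            segments.append(Segment(seg_id, rest.split(field_sep) if rest else []))

    msg = Hl7Message(segments)

    version = msg.version
    if version and version != SUPPORTED_VERSION:
        raise UnsupportedVersionError(
            f"only HL7 v{SUPPORTED_VERSION} is supported, message declares {version!r}"
        )
    mtype = msg.message_type
    base = mtype.split("^")[0]
    if mtype not in SUPPORTED_MESSAGE_TYPES and base != "ACK":
        raise UnsupportedMessageTypeError(
            f"unsupported MSH-9 message type {mtype!r}; "
            f"supported: {sorted(SUPPORTED_MESSAGE_TYPES)}"
        )
    if not msg.control_id:
        raise Hl7StructuralError("MSH-10 control id is empty")
    if profile is not None and profile.facility_codes:
        if msg.sending_facility not in profile.facility_codes:
            raise Hl7StructuralError(
                f"sending facility {msg.sending_facility!r} not expected for "
                f"vendor {profile.vendor_name!r} (expects {sorted(profile.facility_codes)})"
            )
    return msg


def serialize_message(msg: Hl7Message) -> str:
    """Render a message to canonical wire text.

    Trailing empty fields of each segment are trimmed; segments are
    joined with carriage returns. MSH is rendered with MSH-1 as the
    literal separator following the segment id.
    """
    if not msg.segments:
        raise Hl7StructuralError("cannot serialize a message with no segments")
    lines = []
    for seg in msg.segments:
        fields = list(seg.fields)
        while fields and fields[-1] == "":
            fields.pop()
        if seg.segment_id == "MSH":
            if not fields:
                raise Hl7StructuralError("MSH segment has no fields")
            sep = fields[0]
            lines.append("MSH" + sep + sep.join(fields[1:]))
        else:
            sep = msg.field_separator or "|"
            lines.append(seg.segment_id + (sep + sep.join(fields) if fields else ""))
    return SEGMENT_SEP.join(lines) + SEGMENT_SEP


def read_mllp_stream(data: str) -> list[str]:
    """Split an MLLP-framed stream (``\\x0b`` ... ``\\x1c\\x0d``) into raw messages.

    Unframed input containing a single message is returned as-is, so
    file-per-message and stream inputs go through one entry point.
    """
    if MLLP_START not in data:
        stripped = data.strip()
        return [stripped] if stripped else []
    messages = []
    for chunk in data.split(MLLP_START)[1:]:
        body = chunk.split(MLLP_END)[0].strip("\r\n")
        if body:
            messages.append(body)
    return messages
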