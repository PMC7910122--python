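"""Per-vendor dialect profiles.

Different upstream EHRs place the same logical order attribute in
different segments and fields. A profile is declarative config mapping
each logical attribute to a segment/field/component address, plus the
sending-facility codes the vendor uses, so supporting a new vendor
means shipping a new YAML file, not new code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from epichart.errors import ValidationError

#: Logical attributes every profile must address.
LOGICAL_ATTRIBUTES = (
    "mrn",
    "patient_name",
    "dob",
    "sex",
    "procedure_code",
    "placer_id",
    "filler_id",
    "ordering_provider",
    "order_datetime",
)

_KNOWN_SEGMENTS = {"MSH", "PID", "PV1", "ORC", "OBR", "OBX", "FT1", "MSA", "NTE", "DG1"}

_ADDRESS_RE = re.compile(r"^([A-Z][A-Z0-9]{2})-(\d+)(?:\.(\d+))?$")


@dataclass(frozen=True)
class FieldAddress:
    """Segment/field/component address like ``PID-3.1`` (component optional)."""

    segment_id: str
    field: int
    component: int | None = None

    @classmethod
    def parse(cls, text: str) -> "FieldAddress":
        m = _ADDRESS_RE.match(text.strip())
        if not m:
            raise ValidationError(f"malformed field address {text!r}; expected SEG-n[.c]")
        seg, fld, comp = m.group(1), int(m.group(2)), m.group(3)
        if seg not in _KNOWN_SEGMENTS:
            raise ValidationError(f"address {text!r} references unknown segment {seg!r}")
        return cls(seg, fld, int(comp) if comp else None)

    def __str__(self) -> str:
        base = f"{self.segment_id}-{self.field}"
        return f"{base}.{self.component}" if self.component else base


@dataclass
class DialectProfile:
    """Vendor dialect: logical attribute → address, plus facility codes."""

    vendor_name: str
    field_map: dict[str, FieldAddress]
    facility_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [a for a in LOGICAL_ATTRIBUTES if a not in self.field_map]
        extra = [a for a in self.field_map if a not in LOGICAL_ATTRIBUTES]
        if missing or extra:
            raise ValidationError(
                f"profile {self.vendor_name!r} field_map mismatch: "
                f"missing {missing}, unknown {extra}"
            )

    def address(self, attribute: str) -> FieldAddress:
        try:
            return self.field_map[attribute]
        except KeyError:
            raise ValidationError(f"unknown logical attribute {attribute!r}") from None


def _profile(vendor: str, addresses: dict[str, str], facilities: set[str]) -> DialectProfile:
    return DialectProfile(
        vendor_name=vendor,
        field_map={k: FieldAddress.parse(v) for k, v in addresses.items()},
        facility_codes=frozenset(facilities),
    )


def allscripts_profile() -> DialectProfile:
    """Layout used by the university-clinic upstream EHR.

    Order identifiers and the ordering provider travel on OBR; these
    field placements are engine fixtures, not vendor documentation.
    """
    return _profile(
        "allscripts",
        {
            "mrn": "PID-3.1",
            "patient_name": "PID-5",
            "dob": "PID-7",
            "sex": "PID-8",
            "placer_id": "OBR-2",
            "filler_id": "OBR-3",
            "procedure_code": "OBR-4",
            "order_datetime": "OBR-6",
            "ordering_provider": "OBR-16",
        },
        {"UTP", "UTPB"},
    )


def cerner_profile() -> DialectProfile:
    """Layout used by the hospital-system upstream EHR.

    Order identifiers and the ordering provider travel on ORC rather
    than OBR; placements are engine fixtures, not vendor documentation.
    """
    return _profile(
        "cerner",
        {
            "mrn": "PID-3.1",
            "patient_name": "PID-5",
            "dob": "PID-7",
            "sex": "PID-8",
            "placer_id": "ORC-2",
            "filler_id": "ORC-3",
            "procedure_code": "OBR-4",
            "order_datetime": "ORC-9",
            "ordering_provider": "ORC-12",
        },
        {"MHHS", "MHTMC"},
    )


_BUILTIN = {"allscripts": allscripts_profile, "cerner": cerner_profile}


def builtin_profiles() -> dict[str, DialectProfile]:
    return {name: make() for name, make in _BUILTIN.items()}


def get_profile(name: str) -> DialectProfile:
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise ValidationError(
            f"unknown dialect profile {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None


def load_profile(path: str | Path) -> DialectProfile:
    """Load a dialect profile from a YAML file.

    Expected keys: ``vendor_name``, ``field_map`` (attribute → address
    string), ``facility_codes`` (list).
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"profile file {path} does not hold a mapping")
    try:
        return DialectProfile(
            vendor_name=data["vendor_name"],
            field_map={k: FieldAddress.parse(v) for k, v in data["field_map"].items()},
            facility_codes=frozenset(data.get("facility_codes", [])),
        )
    except KeyError as exc:
        raise ValidationError(f"profile file {path} missing key {exc}") from None
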