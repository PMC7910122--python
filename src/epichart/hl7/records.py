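"""Logical records extracted from (or rendered into) HL7 traffic."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from epichart.errors import ValidationError


@dataclass(frozen=True)
class PersonName:
    """Family/given name pair as carried in HL7 XPN/XCN fields."""

    family: str
    given: str = ""

    def to_hl7(self) -> str:
        return f"{self.family}^{self.given}" if self.given else self.family

    @classmethod
    def from_hl7(cls, raw: str) -> "PersonName":
        parts = raw.split("^")
        return cls(family=parts[0], given=parts[1] if len(parts) > 1 else "")


@dataclass
class OrderRecord:
    """Vendor-neutral view of an inbound order.

    Whatever dialect the order arrived in, extraction lands here; the
    only vendor trace is :attr:`source_vendor`.
    """

    mrn: str
    patient_name: PersonName
    dob: dt.date | None
    sex: str
    placer_id: str
    filler_id: str
    procedure_code: str
    procedure_text: str
    ordering_provider: str
    order_datetime: dt.datetime | None
    source_vendor: str

    def __post_init__(self) -> None:
        missing = [name for name, value in
                   [("mrn", self.mrn), ("placer_id", self.placer_id),
                    ("procedure_code", self.procedure_code)] if not value]
        if missing:
            raise ValidationError(
                f"order is missing required attributes: {', '.join(missing)}",
                details=missing,
            )


@dataclass
class ChargeRecord:
    """Billing payload for one report: procedure and diagnosis codes.

    Procedure codes may carry modifiers as ``code:modifier``.
    """

    procedure_codes: list[str]
    diagnosis_codes: list[str]
    billing_provider: str
    service_date: dt.date
    filed_at: dt.datetime = field(default_factory=dt.datetime.now)

    def __post_init__(self) -> None:
        if not self.procedure_codes:
            raise ValidationError("charge must carry at least one procedure code")
        if self.service_date > self.filed_at.date():
            raise ValidationError(
                f"service date {self.service_date} is in the future "
                f"relative to filing time {self.filed_at}"
            )


def parse_hl7_date(raw: str) -> dt.date | None:
    """Parse an HL7 DT value (YYYYMMDD); None for empty input."""
    if not raw:
        return None
    return dt.datetime.strptime(raw[:8], "%Y%m%d").date()


def parse_hl7_timestamp(raw: str) -> dt.datetime | None:
    """Parse an HL7 TS value (YYYYMMDD[HHMMSS]); None for empty input."""
    if not raw:
        return None
    if len(raw) >= 14:
        return dt.datetime.strptime(raw[:14], "%Y%m%d%H%M%S")
    return dt.datetime.strptime(raw[:8], "%Y%m%d")


def format_hl7_date(value: dt.date | None) -> str:
    return value.strftime("%Y%m%d") if value else ""


def format_hl7_timestamp(value: dt.datetime | None) -> str:
    return value.strftime("%Y%m%d%H%M%S") if value else ""
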