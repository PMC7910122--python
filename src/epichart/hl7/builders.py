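"""Message construction and logical-record extraction.

Inbound: :func:`extract_order` turns a parsed ORM into a vendor-neutral
:class:`~epichart.hl7.records.OrderRecord` using a dialect profile.
Outbound: :func:`build_ack`, :func:`build_result` (ORU) and
:func:`build_charge` (DFT) render engine state back into v2.3 text; all
outbound messages re-parse cleanly under :func:`parse_message`.

The rendering of structured vocabulary selections into ORU observations
is an engine convention (one OBX per report section; OBX-5 carries the
escaped narrative followed by one ``id^label^EPSO-LOCAL`` coded
repetition per selected term): the upstream standard does not prescribe
where such codes travel, so receivers must be configured to match.
"""

from __future__ import annotations

import datetime as dt
import itertools
from typing import TYPE_CHECKING

from epichart.errors import StateError, ValidationError
from epichart.hl7.dialect import DialectProfile, FieldAddress
from epichart.hl7.model import (
    COMPONENT_SEP,
    ENCODING_CHARS,
    FIELD_SEP,
    REPETITION_SEP,
    SUPPORTED_VERSION,
    Hl7Message,
    Segment,
    escape_text,
    unescape_text,
)
from epichart.hl7.records import (
    ChargeRecord,
    OrderRecord,
    PersonName,
    format_hl7_date,
    format_hl7_timestamp,
    parse_hl7_date,
    parse_hl7_timestamp,
)

if TYPE_CHECKING:  # pragma: no cover
    from epichart.workflow import Report

ENGINE_APP = "EPICHART"
ENGINE_FACILITY = "EPILEPSY"

_control_counter = itertools.count(1)


def _fresh_control_id(prefix: str = "EC") -> str:
    return f"{prefix}{next(_control_counter):06d}"


def _now_ts() -> str:
    return dt.datetime.now().strftime("%Y%m%d%H%M%S")


def make_msh(
    message_type: str,
    control_id: str,
    *,
    sending_app: str = ENGINE_APP,
    sending_facility: str = ENGINE_FACILITY,
    receiving_app: str = "",
    receiving_facility: str = "",
    timestamp: str | None = None,
) -> Segment:
    return Segment("MSH", [
        FIELD_SEP, ENCODING_CHARS,
        sending_app, sending_facility,
        receiving_app, receiving_facility,
        timestamp if timestamp is not None else _now_ts(),
        "",  # security
        message_type, control_id, "P", SUPPORTED_VERSION,
    ])


# --- address-based get/set --------------------------------------------


def read_address(msg: Hl7Message, addr: FieldAddress) -> str:
    """Value at a profile address; '' when the segment/field is absent."""
    if not msg.has_segment(addr.segment_id):
        return ""
    seg = msg.segment(addr.segment_id)
    if addr.component is None:
        return seg.get(addr.field)
    return seg.component(addr.field, addr.component)


def write_address(seg: Segment, addr: FieldAddress, value: str) -> None:
    if addr.component is None:
        seg.set(addr.field, value)
        return
    parts = seg.get(addr.field).split(COMPONENT_SEP)
    while len(parts) < addr.component:
        parts.append("")
    parts[addr.component - 1] = value
    seg.set(addr.field, COMPONENT_SEP.join(parts))


# --- ACK ---------------------------------------------------------------

ACK_CODES = frozenset({"AA", "AE", "AR"})


def build_ack(
    inbound: Hl7Message,
    code: str,
    *,
    text: str = "",
    control_id: str | None = None,
    timestamp: str | None = None,
) -> Hl7Message:
    """Acknowledge an inbound message.

    MSA-1 carries the acknowledgement code (AA accept, AE application
    error, AR reject) and MSA-2 echoes the inbound control id; the
    sending and receiving application/facility pairs are swapped so the
    ACK routes back to the originator.
    """
    if code not in ACK_CODES:
        raise ValidationError(f"acknowledgement code must be one of {sorted(ACK_CODES)}")
    if not inbound.control_id:
        raise ValidationError("inbound message has no control id to acknowledge")
    msh = make_msh(
        "ACK",
        control_id or _fresh_control_id("ACK"),
        sending_app=inbound.receiving_app or ENGINE_APP,
        sending_facility=inbound.receiving_facility or ENGINE_FACILITY,
        receiving_app=inbound.sending_app,
        receiving_facility=inbound.sending_facility,
        timestamp=timestamp,
    )
    msa = Segment("MSA", [code, inbound.control_id] + ([escape_text(text)] if text else []))
    return Hl7Message([msh, msa])


# --- orders ------------------------------------------------------------


def extract_order(msg: Hl7Message, profile: DialectProfile) -> OrderRecord:
    """Extract a vendor-neutral order record from a parsed ORM.

    Raises :class:`ValidationError` naming every missing required
    logical attribute (mrn, placer_id, procedure_code), so the caller
    can acknowledge with AE and report all problems at once.
    """
    if msg.message_type != "ORM^O01":
        raise StateError(f"expected an ORM^O01 message, got {msg.message_type!r}")

    def value(attr: str) -> str:
        return read_address(msg, profile.address(attr))

    proc_raw = value("procedure_code").split(COMPONENT_SEP)
    provider_raw = value("ordering_provider")
    return OrderRecord(
        mrn=unescape_text(value("mrn")),
        patient_name=PersonName(
            *(unescape_text(p) for p in (value("patient_name").split(COMPONENT_SEP) + [""])[:2])
        ),
        dob=parse_hl7_date(value("dob")),
        sex=value("sex"),
        placer_id=value("placer_id"),
        filler_id=value("filler_id"),
        procedure_code=unescape_text(proc_raw[0]),
        procedure_text=unescape_text(proc_raw[1]) if len(proc_raw) > 1 else "",
        ordering_provider=unescape_text(provider_raw),
        order_datetime=parse_hl7_timestamp(value("order_datetime")),
        source_vendor=profile.vendor_name,
    )


def build_order(
    order: OrderRecord,
    profile: DialectProfile,
    *,
    control_id: str,
    timestamp: str | None = None,
    sending_facility: str | None = None,
) -> Hl7Message:
    """Render a logical order as an ORM^O01 in a vendor's dialect.

    Used by the synthetic order generator and by the cross-dialect
    equivalence checks; real deployments only consume orders.
    """
    if sending_facility is None:
        sending_facility = min(profile.facility_codes) if profile.facility_codes else ""
    msh = make_msh(
        "ORM^O01", control_id,
        sending_app=profile.vendor_name.upper(),
        sending_facility=sending_facility,
        receiving_app=ENGINE_APP, receiving_facility=ENGINE_FACILITY,
        timestamp=timestamp,
    )
    segments: dict[str, Segment] = {}
    for seg_id in ("PID", "ORC", "OBR"):
        if any(a.segment_id == seg_id for a in profile.field_map.values()):
            segments[seg_id] = Segment(seg_id)

    def put(attr: str, value: str) -> None:
        addr = profile.address(attr)
        write_address(segments[addr.segment_id], addr, value)

    put("mrn", escape_text(order.mrn))
    put("patient_name", order.patient_name.to_hl7())
    put("dob", format_hl7_date(order.dob))
    put("sex", order.sex)
    put("placer_id", order.placer_id)
    put("filler_id", order.filler_id)
    proc = escape_text(order.procedure_code)
    if order.procedure_text:
        proc += COMPONENT_SEP + escape_text(order.procedure_text)
    put("procedure_code", proc)
    put("ordering_provider", escape_text(order.ordering_provider))
    put("order_datetime", format_hl7_timestamp(order.order_datetime))

    ordered = [msh] + [segments[s] for s in ("PID", "ORC", "OBR") if s in segments]
    return Hl7Message(ordered)


# --- results (ORU) -----------------------------------------------------


def build_result(
    report: "Report",
    order: OrderRecord,
    profile: DialectProfile,
    *,
    amended: bool = False,
    control_id: str | None = None,
    timestamp: str | None = None,
) -> Hl7Message:
    """Render a finalized report as an ORU^R01 addressed to the order's vendor.

    One OBX per populated report section, in schema order; OBX-11 is
    ``F`` (final) or ``C`` (correction) for post-transmission
    amendments. OBR placer/filler ids echo the originating order so the
    parent EHR can match result to order.
    """
    from epichart.workflow import ReportState  # local import to avoid a cycle

    if report.state < ReportState.FINALIZED:
        raise StateError(
            f"report {report.report_id} is {report.state.name}; "
            "results are built only for finalized reports"
        )
    receiving_fac = min(profile.facility_codes) if profile.facility_codes else ""
    msh = make_msh(
        "ORU^R01", control_id or _fresh_control_id("ORU"),
        receiving_app=profile.vendor_name.upper(),
        receiving_facility=receiving_fac,
        timestamp=timestamp,
    )
    pid = Segment("PID")
    pid.set(3, escape_text(order.mrn))
    pid.set(5, order.patient_name.to_hl7())
    pid.set(7, format_hl7_date(order.dob))
    pid.set(8, order.sex)
    obr = Segment("OBR")
    obr.set(2, order.placer_id)
    obr.set(3, order.filler_id)
    proc = escape_text(order.procedure_code)
    if order.procedure_text:
        proc += COMPONENT_SEP + escape_text(order.procedure_text)
    obr.set(4, proc)
    obr.set(25, "F")
    segments = [msh, pid, obr]
    status = "C" if amended else "F"
    for i, (section_name, payload) in enumerate(report.populated_sections(), start=1):
        obx = Segment("OBX")
        obx.set(1, str(i))
        obx.set(2, "CE" if payload.term_ids() else "TX")
        obx.set(3, escape_text(section_name))
        reps = [escape_text(payload.narrative)]
        reps += [f"{escape_text(tid)}^{escape_text(label)}^EPSO-LOCAL"
                 for tid, label in payload.coded_entries()]
        obx.set(5, REPETITION_SEP.join(reps))
        obx.set(11, status)
        segments.append(obx)
    return Hl7Message(segments)


# --- charges (DFT) -----------------------------------------------------


def build_charge(
    report: "Report",
    charge: ChargeRecord,
    profile: DialectProfile,
    *,
    control_id: str | None = None,
    timestamp: str | None = None,
) -> Hl7Message:
    """Render a billing event as a DFT^P03 with one FT1 per procedure code.

    Requires the report to have been transmitted and its transmission
    accepted; the billing provider on every FT1 is the report's
    attributed physician.
    """
    from epichart.workflow import ReportState

    if report.state < ReportState.TRANSMITTED:
        raise StateError(
            f"report {report.report_id} is {report.state.name}; "
            "billing requires an accepted transmission"
        )
    if not charge.procedure_codes:
        raise ValidationError("charge carries no procedure codes")
    provider = report.attributed_physician or charge.billing_provider
    receiving_fac = min(profile.facility_codes) if profile.facility_codes else ""
    msh = make_msh(
        "DFT^P03", control_id or _fresh_control_id("DFT"),
        receiving_app=profile.vendor_name.upper(),
        receiving_facility=receiving_fac,
        timestamp=timestamp,
    )
    pid = Segment("PID")
    pid.set(3, escape_text(report.patient_mrn))
    segments = [msh, pid]
    for i, code in enumerate(charge.procedure_codes, start=1):
        proc, _, modifier = code.partition(":")
        ft1 = Segment("FT1")
        ft1.set(1, str(i))
        ft1.set(4, format_hl7_date(charge.service_date))
        ft1.set(6, "CG")
        ft1.set(7, escape_text(proc))
        if modifier:
            ft1.set(26, escape_text(modifier))
        if charge.diagnosis_codes:
            ft1.set(19, REPETITION_SEP.join(escape_text(d) for d in charge.diagnosis_codes))
        ft1.set(20, escape_text(provider))
        segments.append(ft1)
    return Hl7Message(segments)
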