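"""Collaborative report lifecycle.

An inbound order becomes a report document that moves through a strict
forward-only pipeline::

    AWAITING_TECHNICIAN → TECHNICIAN_COMPLETED → FELLOW_COMPLETED
        → FINALIZED → TRANSMITTED → BILLED

Technicians document the recording, fellows enter interpretations,
attendings review and finalize; transmission sends the result back to
the parent EHR and advances only once the parent acknowledges with AA;
billing follows an accepted transmission. Every transition is
role-gated through the access policy and appended to an audit trail
that can be replayed against the allowed-transition table.

Two deliberate escape hatches exist, both audited: attendings may
finalize directly from TECHNICIAN_COMPLETED (fellow step skipped —
staffing realities), and post-transmission amendments produce a new
correction result message rather than mutating history.
"""

from __future__ import annotations

import datetime as dt
import enum
import itertools
from dataclasses import dataclass, field, replace

from epichart.errors import (
    DuplicateOrderError,
    MappingError,
    StateError,
    ValidationError,
)
from epichart.hl7 import (
    ChargeRecord,
    DialectProfile,
    Hl7Message,
    OrderRecord,
    build_charge,
    build_result,
)
from epichart.ontology import Category, Ontology, validate_entry
from epichart.rbac import AccessPolicy, Role, User, default_policy, require


class ReportState(enum.IntEnum):
    """Lifecycle states; integer order is pipeline order."""

    AWAITING_TECHNICIAN = 0
    TECHNICIAN_COMPLETED = 1
    FELLOW_COMPLETED = 2
    FINALIZED = 3
    TRANSMITTED = 4
    BILLED = 5


class ReportTypeCode(enum.Enum):
    EEG = "EEG"
    EMU_PHASE = "EMU_PHASE"
    EMU_DAILY = "EMU_DAILY"
    EVOKED_POTENTIALS = "EVOKED_POTENTIALS"


@dataclass(frozen=True)
class SectionSpec:
    """One section of a report schema: who writes it, what vocabulary it uses."""

    name: str
    role: Role
    required_categories: tuple[Category, ...] = ()


@dataclass(frozen=True)
class ReportType:
    code: ReportTypeCode
    status: str  # "production" | "test"
    section_schema: tuple[SectionSpec, ...]
    production_date: dt.date | None = None

    def section(self, name: str) -> SectionSpec:
        for s in self.section_schema:
            if s.name == name:
                return s
        raise ValidationError(
            f"report type {self.code.value} has no section {name!r}; "
            f"schema: {[s.name for s in self.section_schema]}"
        )


def _standard_schema() -> tuple[SectionSpec, ...]:
    return (
        SectionSpec("technician_findings", Role.EEG_TECHNICIAN,
                    (Category.EEG_ACTIVITY,)),
        SectionSpec("fellow_interpretation", Role.CLINICAL_FELLOW,
                    (Category.EEG_ACTIVITY, Category.SEMIOLOGY)),
        SectionSpec("attending_review", Role.ATTENDING_PHYSICIAN,
                    (Category.EPILEPTIC_DIAGNOSIS,)),
    )


def default_report_types() -> dict[ReportTypeCode, ReportType]:
    """The four registered report types.

    EEG, EMU phase and EMU daily reporting run in production (dates are
    each type's production start); evoked potentials is registered in
    test status with no section schema yet. Daily reports include the
    technician stage by default; schemas are config, not code contract.
    """
    return {
        ReportTypeCode.EEG: ReportType(
            ReportTypeCode.EEG, "production", _standard_schema(),
            dt.date(2019, 2, 18)),
        ReportTypeCode.EMU_PHASE: ReportType(
            ReportTypeCode.EMU_PHASE, "production", _standard_schema(),
            dt.date(2019, 7, 1)),
        ReportTypeCode.EMU_DAILY: ReportType(
            ReportTypeCode.EMU_DAILY, "production", _standard_schema(),
            dt.date(2019, 11, 15)),
        ReportTypeCode.EVOKED_POTENTIALS: ReportType(
            ReportTypeCode.EVOKED_POTENTIALS, "test", ()),
    }


#: Map from HL7 procedure codes to report types (extendable config).
DEFAULT_PROCEDURE_MAP: dict[str, ReportTypeCode] = {
    "EEG": ReportTypeCode.EEG,
    "LTM": ReportTypeCode.EEG,          # long-term monitoring EEG read
    "EMUPH": ReportTypeCode.EMU_PHASE,
    "EMUD": ReportTypeCode.EMU_DAILY,
    "EP": ReportTypeCode.EVOKED_POTENTIALS,
}


@dataclass
class SectionPayload:
    """What a clinician enters into one section.

    ``terms`` maps a vocabulary category to the term ids selected for
    it; ``term_labels`` is filled from the ontology at submission so
    outbound coded entries carry display text without another lookup.
    """

    narrative: str = ""
    terms: dict[Category, list[str]] = field(default_factory=dict)
    medications: list[str] = field(default_factory=list)
    term_labels: dict[str, str] = field(default_factory=dict)

    def term_ids(self) -> list[str]:
        return [tid for tids in self.terms.values() for tid in tids]

    def coded_entries(self) -> list[tuple[str, str]]:
        return [(tid, self.term_labels.get(tid, "")) for tid in self.term_ids()]


@dataclass(frozen=True)
class AuditEntry:
    actor: str
    role: str
    transition: str
    timestamp: dt.datetime
    note: str = ""


@dataclass(frozen=True)
class Notification:
    audience: str
    subject: str
    timestamp: dt.datetime


#: transition label → roles allowed to perform it (audit replay contract).
ALLOWED_TRANSITIONS: dict[str, frozenset[Role]] = {
    "created": frozenset(Role),  # system-triggered on order ingest
    "technician_section_submitted": frozenset({Role.EEG_TECHNICIAN, Role.ADMIN}),
    "fellow_section_submitted": frozenset({Role.CLINICAL_FELLOW, Role.ADMIN}),
    "attending_section_submitted": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
    "finalized": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
    "transmission_attempted": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
    "transmitted": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
    "transmission_rejected": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
    "billed": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
    "amended": frozenset({Role.ATTENDING_PHYSICIAN, Role.ADMIN}),
}

_SECTION_TRANSITION = {
    Role.EEG_TECHNICIAN: "technician_section_submitted",
    Role.CLINICAL_FELLOW: "fellow_section_submitted",
    Role.ATTENDING_PHYSICIAN: "attending_section_submitted",
}

_SECTION_ACTION = {
    Role.EEG_TECHNICIAN: "submit_technician_section",
    Role.CLINICAL_FELLOW: "submit_fellow_section",
    Role.ATTENDING_PHYSICIAN: "submit_attending_section",
}

#: state a section submission must find the report in
_SECTION_PRECONDITION = {
    Role.EEG_TECHNICIAN: ReportState.AWAITING_TECHNICIAN,
    Role.CLINICAL_FELLOW: ReportState.TECHNICIAN_COMPLETED,
    Role.ATTENDING_PHYSICIAN: ReportState.FELLOW_COMPLETED,
}

#: state after a section submission (attending section does not advance;
#: finalization is its own audited act)
_SECTION_POSTSTATE = {
    Role.EEG_TECHNICIAN: ReportState.TECHNICIAN_COMPLETED,
    Role.CLINICAL_FELLOW: ReportState.FELLOW_COMPLETED,
    Role.ATTENDING_PHYSICIAN: ReportState.FELLOW_COMPLETED,
}


@dataclass
class Report:
    report_id: str
    type: ReportType
    order: OrderRecord
    patient_mrn: str
    state: ReportState = ReportState.AWAITING_TECHNICIAN
    sections: dict[str, SectionPayload] = field(default_factory=dict)
    attributed_physician: str = ""
    audit: list[AuditEntry] = field(default_factory=list)
    finalized_at: dt.datetime | None = None
    transmission_pending: bool = False
    amended: bool = False

    def populated_sections(self) -> list[tuple[str, SectionPayload]]:
        """Populated sections in schema order."""
        return [(s.name, self.sections[s.name])
                for s in self.type.section_schema if s.name in self.sections]

    def record(self, actor: User | None, role: Role | None, transition: str,
               now: dt.datetime, note: str = "") -> None:
        if self.audit and now < self.audit[-1].timestamp:
            now = self.audit[-1].timestamp  # clock skew: clamp, never go back
        self.audit.append(AuditEntry(
            actor.user_id if actor else "system",
            role.value if role else "system",
            transition, now, note))


def replay_audit(report: Report) -> None:
    """Validate a report's audit trail against the transition table.

    Raises :class:`ValidationError` on an unknown transition, a role
    not allowed to perform it, or timestamps that go backwards.
    """
    last = None
    for entry in report.audit:
        if entry.transition not in ALLOWED_TRANSITIONS:
            raise ValidationError(f"unknown transition {entry.transition!r} in audit")
        if entry.role != "system":
            role = Role(entry.role)
            if role not in ALLOWED_TRANSITIONS[entry.transition]:
                raise ValidationError(
                    f"role {entry.role} may not perform {entry.transition!r}")
        if last is not None and entry.timestamp < last:
            raise ValidationError("audit timestamps decrease")
        last = entry.timestamp


class ReportService:
    """Registry plus the operations that move reports through the pipeline.

    Holds the access policy, the vocabulary used to validate structured
    entries, and the registered report types. Reports are kept in
    memory keyed by report id, with a placer-id index enforcing
    ingest-once semantics.
    """

    def __init__(
        self,
        policy: AccessPolicy | None = None,
        ontology: Ontology | None = None,
        report_types: dict[ReportTypeCode, ReportType] | None = None,
        procedure_map: dict[str, ReportTypeCode] | None = None,
        clock=dt.datetime.now,
    ):
        self.policy = policy or default_policy()
        self.ontology = ontology
        self.report_types = report_types or default_report_types()
        self.procedure_map = dict(procedure_map or DEFAULT_PROCEDURE_MAP)
        self.clock = clock
        self.reports: dict[str, Report] = {}
        self._by_placer: dict[str, str] = {}
        self.notifications: list[Notification] = []
        self._ids = itertools.count(1)

    # -- creation ------------------------------------------------------

    def create_report_from_order(self, order: OrderRecord) -> Report:
        """Open a report document for an inbound order and notify technicians."""
        if order.placer_id in self._by_placer:
            raise DuplicateOrderError(
                f"order {order.placer_id!r} was already ingested as report "
                f"{self._by_placer[order.placer_id]}")
        try:
            type_code = self.procedure_map[order.procedure_code]
        except KeyError:
            raise MappingError(
                f"procedure code {order.procedure_code!r} maps to no registered "
                f"report type; known codes: {sorted(self.procedure_map)}") from None
        report = Report(
            report_id=f"R{next(self._ids):06d}",
            type=self.report_types[type_code],
            order=order,
            patient_mrn=order.mrn,
        )
        now = self.clock()
        report.record(None, None, "created", now,
                      note=f"order {order.placer_id} from {order.source_vendor}")
        self.reports[report.report_id] = report
        self._by_placer[order.placer_id] = report.report_id
        self.notifications.append(Notification(
            "eeg_technicians", f"report {report.report_id} awaiting technician", now))
        return report

    # -- section submission --------------------------------------------

    def submit_section(self, report: Report, actor: User, section: str,
                       payload: SectionPayload) -> Report:
        """Store a section payload and advance the pipeline stage.

        The actor must hold the role the schema assigns to the section;
        the report must sit exactly one stage before that section's
        completion; structured terms must validate against the
        vocabulary for the categories the section declares.
        """
        spec = report.type.section(section)
        require(self.policy, actor, _SECTION_ACTION[spec.role], "report")
        if not actor.has_role(spec.role) and not actor.has_role(Role.ADMIN):
            # policy may be customised; the schema role still binds
            raise StateError(
                f"section {section!r} belongs to role {spec.role.value}")
        expected = _SECTION_PRECONDITION[spec.role]
        if report.state != expected:
            raise StateError(
                f"section {section!r} requires state {expected.name}, "
                f"report {report.report_id} is {report.state.name}")
        self._validate_terms(payload)
        resolved = self._resolve_labels(payload)
        report.sections[section] = resolved
        report.state = _SECTION_POSTSTATE[spec.role]
        report.record(actor, spec.role, _SECTION_TRANSITION[spec.role], self.clock(),
                      note=section)
        return report

    def _validate_terms(self, payload: SectionPayload) -> None:
        if not payload.terms:
            return
        if self.ontology is None:
            raise ValidationError("structured terms supplied but no ontology loaded")
        problems: list[str] = []
        for category, tids in payload.terms.items():
            for v in validate_entry(self.ontology, category, tids):
                problems.append(f"{v.term_id}: {v.reason} ({v.detail})")
        if problems:
            raise ValidationError("invalid structured entries", details=problems)

    def _resolve_labels(self, payload: SectionPayload) -> SectionPayload:
        labels = dict(payload.term_labels)
        if self.ontology is not None:
            for tid in payload.term_ids():
                labels[tid] = self.ontology.terms[tid].label
        return replace(payload, term_labels=labels)

    # -- finalization --------------------------------------------------

    def finalize_report(self, report: Report, actor: User, schedule=None,
                        claim: str | None = None) -> Report:
        """Attending review: close the document and attribute it.

        Attribution defaults to the physician on service for the
        report's type on the finalization date (via the service
        schedule); an explicit ``claim`` overrides. Finalizing straight
        from TECHNICIAN_COMPLETED is allowed but audit-flagged.
        """
        require(self.policy, actor, "finalize", "report")
        skipped_fellow = report.state == ReportState.TECHNICIAN_COMPLETED
        if report.state not in (ReportState.FELLOW_COMPLETED,
                                ReportState.TECHNICIAN_COMPLETED):
            raise StateError(
                f"cannot finalize from {report.state.name}; expected "
                "FELLOW_COMPLETED (or TECHNICIAN_COMPLETED with override)")
        now = self.clock()
        report.finalized_at = now
        if claim:
            report.attributed_physician = claim
        elif schedule is not None:
            from epichart.dashboard import attribute_report
            report.attributed_physician = attribute_report(report, schedule)
        else:
            report.attributed_physician = actor.user_id
        report.state = ReportState.FINALIZED
        report.record(actor, Role.ATTENDING_PHYSICIAN, "finalized", now,
                      note="fellow-step-skipped" if skipped_fellow else "")
        return report

    # -- transmission --------------------------------------------------

    def transmit_report(self, report: Report, profile: DialectProfile,
                        actor: User | None = None) -> Hl7Message:
        """Build the outbound result message and mark transmission pending.

        The state advances only when :meth:`register_ack` records an AA
        from the parent EHR; a rejection leaves the report FINALIZED
        with an audit note so it can be corrected and resent.
        """
        if actor is not None:
            require(self.policy, actor, "transmit", "report")
        if report.state != ReportState.FINALIZED:
            raise StateError(
                f"cannot transmit from {report.state.name}; report must be FINALIZED"
                + (" (already transmitted; amend instead)"
                   if report.state >= ReportState.TRANSMITTED else ""))
        oru = build_result(report, report.order, profile)
        report.transmission_pending = True
        report.record(actor, Role.ATTENDING_PHYSICIAN, "transmission_attempted",
                      self.clock(), note=oru.control_id)
        return oru

    def register_ack(self, report: Report, ack: Hl7Message | str) -> Report:
        """Apply the parent EHR's acknowledgement of a pending transmission."""
        code = ack if isinstance(ack, str) else ack.segment("MSA").get(1)
        if not report.transmission_pending:
            raise StateError(f"report {report.report_id} has no pending transmission")
        report.transmission_pending = False
        if code == "AA":
            report.state = ReportState.TRANSMITTED
            report.record(None, None, "transmitted", self.clock())
        else:
            report.record(None, None, "transmission_rejected", self.clock(),
                          note=f"ack {code}")
        return report

    # -- billing -------------------------------------------------------

    def file_billing(self, report: Report, actor: User, charge: ChargeRecord,
                     profile: DialectProfile) -> Hl7Message:
        """File charges for an accepted report; emits the DFT and closes the pipeline."""
        require(self.policy, actor, "bill", "report")
        if report.state != ReportState.TRANSMITTED:
            raise StateError(
                f"cannot bill from {report.state.name}; billing requires an "
                "accepted transmission")
        dft = build_charge(report, charge, profile)
        report.state = ReportState.BILLED
        report.record(actor, Role.ATTENDING_PHYSICIAN, "billed", self.clock(),
                      note=",".join(charge.procedure_codes))
        return dft

    # -- amendment (post-transmission correction) ----------------------

    def amend_section(self, report: Report, actor: User, section: str,
                      payload: SectionPayload) -> Report:
        """Replace a section after transmission; history is never rewritten."""
        require(self.policy, actor, "finalize", "report")
        if report.state < ReportState.TRANSMITTED:
            raise StateError("amendment applies only after transmission; "
                             "use submit_section before that")
        report.type.section(section)  # must be schema-declared
        self._validate_terms(payload)
        report.sections[section] = self._resolve_labels(payload)
        report.amended = True
        report.record(actor, Role.ATTENDING_PHYSICIAN, "amended", self.clock(),
                      note=section)
        return report

    def transmit_amendment(self, report: Report, profile: DialectProfile) -> Hl7Message:
        """Correction result (observation status C) for an amended report."""
        if not report.amended:
            raise StateError(f"report {report.report_id} has no amendment to send")
        return build_result(report, report.order, profile, amended=True)

    # -- queries -------------------------------------------------------

    def outstanding_reports(self, actor: User, as_of: dt.date | None = None) -> list[Report]:
        """Reports awaiting the actor's role's action, oldest order first.

        Technicians see AWAITING_TECHNICIAN, fellows TECHNICIAN_COMPLETED;
        attendings see FELLOW_COMPLETED plus TECHNICIAN_COMPLETED (which
        they may finalize under the audited override).
        """
        wanted: set[ReportState] = set()
        if actor.has_role(Role.EEG_TECHNICIAN) or actor.has_role(Role.ADMIN):
            wanted.add(ReportState.AWAITING_TECHNICIAN)
        if actor.has_role(Role.CLINICAL_FELLOW) or actor.has_role(Role.ADMIN):
            wanted.add(ReportState.TECHNICIAN_COMPLETED)
        if actor.has_role(Role.ATTENDING_PHYSICIAN) or actor.has_role(Role.ADMIN):
            wanted.add(ReportState.FELLOW_COMPLETED)
            wanted.add(ReportState.TECHNICIAN_COMPLETED)
        out = [r for r in self.reports.values() if r.state in wanted]
        if as_of is not None:
            out = [r for r in out
                   if r.order.order_datetime is None
                   or r.order.order_datetime.date() <= as_of]
        return sorted(out, key=lambda r: (
            r.order.order_datetime or dt.datetime.min, r.report_id))

    def state_census(self) -> dict[ReportState, int]:
        census = {s: 0 for s in ReportState}
        for r in self.reports.values():
            census[r.state] += 1
        return census
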