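"""Report lifecycle: role-gated transitions, audit, and registry queries."""

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from epichart.errors import (
    DuplicateOrderError,
    MappingError,
    PermissionError_,
    StateError,
    ValidationError,
)
from epichart.ontology import Category
from epichart.rbac import Role, User
from epichart.workflow import (
    ALLOWED_TRANSITIONS,
    ReportService,
    ReportState,
    ReportTypeCode,
    SectionPayload,
    default_report_types,
    replay_audit,
)

from conftest import make_order


class TestCreate:
    def test_order_opens_awaiting_technician(self, service):
        report = service.create_report_from_order(make_order())
        assert report.state is ReportState.AWAITING_TECHNICIAN
        assert report.type.code is ReportTypeCode.EEG
        assert len(report.audit) == 1
        assert service.notifications[-1].audience == "eeg_technicians"

    def test_unmapped_procedure_code(self, service):
        with pytest.raises(MappingError, match="MRI"):
            service.create_report_from_order(make_order(procedure="MRI"))

    def test_duplicate_placer_id(self, service):
        service.create_report_from_order(make_order(placer="PL0009"))
        with pytest.raises(DuplicateOrderError):
            service.create_report_from_order(make_order(placer="PL0009"))

    def test_four_types_registered_one_in_test(self):
        types = default_report_types()
        assert len(types) == 4
        assert types[ReportTypeCode.EVOKED_POTENTIALS].status == "test"
        assert sum(t.status == "production" for t in types.values()) == 3


class TestSections:
    def test_technician_submission_advances(self, service, technician):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("21-channel recording"))
        assert report.state is ReportState.TECHNICIAN_COMPLETED

    def test_fellow_submission_advances(self, service, technician, fellow):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("recording"))
        service.submit_section(report, fellow, "fellow_interpretation",
                               SectionPayload("interpretation"))
        assert report.state is ReportState.FELLOW_COMPLETED

    def test_out_of_order_submission(self, service, fellow):
        report = service.create_report_from_order(make_order())
        with pytest.raises(StateError):
            service.submit_section(report, fellow, "fellow_interpretation",
                                   SectionPayload("too early"))

    def test_wrong_role_denied(self, service, fellow):
        report = service.create_report_from_order(make_order())
        with pytest.raises(PermissionError_):
            service.submit_section(report, fellow, "technician_findings",
                                   SectionPayload("not my section"))

    def test_invalid_terms_listed(self, service, technician):
        report = service.create_report_from_order(make_order())
        payload = SectionPayload("notes", {Category.EEG_ACTIVITY: ["EEGA110", "BOGUS"]})
        with pytest.raises(ValidationError) as err:
            service.submit_section(report, technician, "technician_findings", payload)
        assert any("BOGUS" in d for d in err.value.details)
        assert report.state is ReportState.AWAITING_TECHNICIAN

    def test_undeclared_section_rejected(self, service, technician):
        report = service.create_report_from_order(make_order())
        with pytest.raises(ValidationError):
            service.submit_section(report, technician, "no_such_section",
                                   SectionPayload("x"))


class TestFinalize:
    def _fellow_completed(self, service, technician, fellow):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("recording"))
        service.submit_section(report, fellow, "fellow_interpretation",
                               SectionPayload("interpretation"))
        return report

    def test_attending_finalizes(self, service, technician, fellow, attending):
        report = self._fellow_completed(service, technician, fellow)
        service.finalize_report(report, attending)
        assert report.state is ReportState.FINALIZED
        assert report.attributed_physician

    def test_technician_cannot_finalize(self, service, technician, fellow):
        report = self._fellow_completed(service, technician, fellow)
        with pytest.raises(PermissionError_):
            service.finalize_report(report, technician)

    def test_fellow_skip_is_audited(self, service, technician, attending):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("recording"))
        service.finalize_report(report, attending)
        assert report.state is ReportState.FINALIZED
        assert report.audit[-1].note == "fellow-step-skipped"

    def test_explicit_claim_overrides_attribution(self, service, technician,
                                                  fellow, attending):
        report = self._fellow_completed(service, technician, fellow)
        service.finalize_report(report, attending, claim="DRCRUZ")
        assert report.attributed_physician == "DRCRUZ"


class TestTransmitAndBill:
    def _finalized(self, service, technician, fellow, attending):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("recording"))
        service.submit_section(report, fellow, "fellow_interpretation",
                               SectionPayload("interpretation"))
        service.finalize_report(report, attending)
        return report

    def test_aa_ack_advances_to_transmitted(self, service, technician, fellow,
                                            attending, profiles):
        report = self._finalized(service, technician, fellow, attending)
        oru = service.transmit_report(report, profiles["cerner"], actor=attending)
        assert oru.message_type == "ORU^R01"
        assert report.state is ReportState.FINALIZED  # pending until ACK
        service.register_ack(report, "AA")
        assert report.state is ReportState.TRANSMITTED

    def test_ae_ack_leaves_finalized_with_audit(self, service, technician, fellow,
                                                attending, profiles):
        report = self._finalized(service, technician, fellow, attending)
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AE")
        assert report.state is ReportState.FINALIZED
        assert report.audit[-1].transition == "transmission_rejected"

    def test_retransmission_without_amendment_rejected(self, service, technician,
                                                       fellow, attending, profiles):
        report = self._finalized(service, technician, fellow, attending)
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AA")
        with pytest.raises(StateError):
            service.transmit_report(report, profiles["cerner"], actor=attending)

    def test_billing_requires_accepted_transmission(self, service, technician, fellow,
                                                    attending, profiles):
        from epichart.hl7.records import ChargeRecord

        report = self._finalized(service, technician, fellow, attending)
        charge = ChargeRecord(["95816"], [], "att1", dt.date(2020, 3, 16),
                              filed_at=dt.datetime(2020, 3, 17))
        with pytest.raises(StateError):
            service.file_billing(report, attending, charge, profiles["cerner"])
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AA")
        dft = service.file_billing(report, attending, charge, profiles["cerner"])
        assert dft.message_type == "DFT^P03"
        assert report.state is ReportState.BILLED

    def test_fellow_cannot_bill(self, service, technician, fellow, attending, profiles):
        from epichart.hl7.records import ChargeRecord

        report = self._finalized(service, technician, fellow, attending)
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AA")
        charge = ChargeRecord(["95816"], [], "x", dt.date(2020, 3, 16),
                              filed_at=dt.datetime(2020, 3, 17))
        with pytest.raises(PermissionError_):
            service.file_billing(report, fellow, charge, profiles["cerner"])

    def test_amendment_produces_correction(self, service, technician, fellow,
                                           attending, profiles):
        report = self._finalized(service, technician, fellow, attending)
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AA")
        service.amend_section(report, attending, "attending_review",
                              SectionPayload("amended impression"))
        oru = service.transmit_amendment(report, profiles["cerner"])
        assert all(o.get(11) == "C" for o in oru.all_segments("OBX"))
        assert report.state is ReportState.TRANSMITTED  # state never rewinds


class TestOutstanding:
    def _populate(self, service, technician, fellow, attending, profiles):
        states = []
        for i in range(8):
            report = service.create_report_from_order(
                make_order(placer=f"PL{i:04d}",
                           when=dt.datetime(2020, 3, 1 + i, 8, 0)))
            states.append(report)
        for report in states[2:]:
            service.submit_section(report, technician, "technician_findings",
                                   SectionPayload("r"))
        for report in states[4:]:
            service.submit_section(report, fellow, "fellow_interpretation",
                                   SectionPayload("i"))
        for report in states[7:]:
            service.finalize_report(report, attending)
            service.transmit_report(report, profiles["cerner"], actor=attending)
            service.register_ack(report, "AA")
        return states

    def test_matches_brute_force_scan(self, service, technician, fellow,
                                      attending, profiles):
        self._populate(service, technician, fellow, attending, profiles)
        for actor, wanted in [
            (technician, {ReportState.AWAITING_TECHNICIAN}),
            (fellow, {ReportState.TECHNICIAN_COMPLETED}),
            (attending, {ReportState.FELLOW_COMPLETED, ReportState.TECHNICIAN_COMPLETED}),
        ]:
            expected = sorted(
                (r for r in service.reports.values() if r.state in wanted),
                key=lambda r: r.order.order_datetime)
            assert service.outstanding_reports(actor) == expected

    def test_sorted_oldest_first(self, service, technician, fellow, attending, profiles):
        self._populate(service, technician, fellow, attending, profiles)
        result = service.outstanding_reports(attending)
        dts = [r.order.order_datetime for r in result]
        assert dts == sorted(dts)

    def test_empty_registry(self, service, attending):
        assert service.outstanding_reports(attending) == []

    def test_conservation(self, service, technician, fellow, attending, profiles):
        """No report is lost or duplicated across states."""
        self._populate(service, technician, fellow, attending, profiles)
        census = service.state_census()
        assert sum(census.values()) == len(service.reports) == 8


class TestAuditReplay:
    def test_full_lifecycle_replays_clean(self, service, technician, fellow,
                                          attending, profiles):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("r"))
        service.submit_section(report, fellow, "fellow_interpretation",
                               SectionPayload("i"))
        service.finalize_report(report, attending)
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AA")
        replay_audit(report)
        transitions = [e.transition for e in report.audit]
        assert transitions == ["created", "technician_section_submitted",
                               "fellow_section_submitted", "finalized",
                               "transmission_attempted", "transmitted"]

    def test_forged_role_detected(self, service, technician):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("r"))
        entry = report.audit[-1]
        report.audit[-1] = type(entry)(entry.actor, Role.CLINICAL_FELLOW.value,
                                       entry.transition, entry.timestamp)
        with pytest.raises(ValidationError):
            replay_audit(report)


@given(ops=st.lists(st.sampled_from(
    ["tech", "fellow", "finalize", "transmit", "ack_aa", "ack_ae", "bill"]),
    min_size=0, max_size=25))
def test_random_operation_sequences_preserve_invariants(ops):
    """Under arbitrary operation sequences, state only moves forward,
    illegal calls raise instead of corrupting, and the report count is
    conserved."""
    from epichart import fixtures as fx
    from epichart.hl7.dialect import cerner_profile
    from epichart.hl7.records import ChargeRecord

    service = ReportService(ontology=fx.mini_ontology())
    profile = cerner_profile()
    technician = User("t", "t", frozenset({Role.EEG_TECHNICIAN}))
    fellow = User("f", "f", frozenset({Role.CLINICAL_FELLOW}))
    attending = User("a", "a", frozenset({Role.ATTENDING_PHYSICIAN}))
    report = service.create_report_from_order(make_order())
    last_state = report.state
    for op in ops:
        try:
            if op == "tech":
                service.submit_section(report, technician, "technician_findings",
                                       SectionPayload("r"))
            elif op == "fellow":
                service.submit_section(report, fellow, "fellow_interpretation",
                                       SectionPayload("i"))
            elif op == "finalize":
                service.finalize_report(report, attending)
            elif op == "transmit":
                service.transmit_report(report, profile, actor=attending)
            elif op == "ack_aa":
                service.register_ack(report, "AA")
            elif op == "ack_ae":
                service.register_ack(report, "AE")
            elif op == "bill":
                charge = ChargeRecord(["95816"], [], "a", dt.date(2020, 1, 2),
                                      filed_at=dt.datetime(2020, 1, 3))
                service.file_billing(report, attending, charge, profile)
        except (StateError, PermissionError_):
            pass
        assert report.state >= last_state, "state regressed"
        last_state = report.state
        assert len(service.reports) == 1
    replay_audit(report)
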