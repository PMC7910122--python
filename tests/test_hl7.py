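"""HL7 v2.3 engine: parsing, serialization, dialects, and message building."""

import datetime as dt

import pytest

from epichart import fixtures as fx
from epichart.errors import (
    Hl7EncodingError,
    Hl7StructuralError,
    StateError,
    UnsupportedMessageTypeError,
    UnsupportedVersionError,
    ValidationError,
)
from epichart.hl7 import (
    build_ack,
    build_charge,
    build_result,
    extract_order,
    parse_message,
    read_mllp_stream,
    serialize_message,
)
from epichart.hl7.builders import build_order
from epichart.hl7.model import Segment, escape_text, unescape_text
from epichart.hl7.records import ChargeRecord
from epichart.ontology import Category
from epichart.rbac import Role, User
from epichart.workflow import ReportService, SectionPayload

from conftest import make_order

ORM_TEXT = (
    "MSH|^~\\&|CERNER|MHTMC|EPICHART|EPILEPSY|20200315093000||ORM^O01|CTL001|P|2.3\r"
    "PID|||MRN00042||DOE^JANE||19800601|F\r"
    "ORC||PL0001|FL0001||||||20200315093000|||DRFOX\r"
    "OBR||||EEG^Electroencephalogram\r"
)


class TestParse:
    def test_constructed_orm_populates_header(self):
        msg = parse_message(ORM_TEXT)
        assert msg.message_type == "ORM^O01"
        assert msg.control_id == "CTL001"
        assert msg.sending_facility == "MHTMC"
        assert msg.version == "2.3"
        assert [s.segment_id for s in msg.segments] == ["MSH", "PID", "ORC", "OBR"]

    def test_field_repetitions_split_on_tilde(self):
        text = ORM_TEXT.replace("MRN00042", "111~222")
        msg = parse_message(text)
        assert msg.segment("PID").repetitions(3) == ["111", "222"]

    def test_newline_separators_accepted(self):
        msg = parse_message(ORM_TEXT.replace("\r", "\n"))
        assert msg.control_id == "CTL001"

    def test_unknown_segments_preserved(self):
        text = ORM_TEXT + "ZXT|custom|payload\r"
        msg = parse_message(text)
        assert msg.segment("ZXT").get(2) == "payload"
        assert serialize_message(msg) == text

    def test_missing_msh_is_structural_error(self):
        with pytest.raises(Hl7StructuralError):
            parse_message("PID|||MRN1\r")

    def test_unsupported_type_names_msh9(self):
        with pytest.raises(UnsupportedMessageTypeError, match="ADT"):
            parse_message(ORM_TEXT.replace("ORM^O01", "ADT^A01"))

    def test_other_versions_rejected(self):
        with pytest.raises(UnsupportedVersionError):
            parse_message(ORM_TEXT.replace("|2.3", "|2.5"))

    def test_bad_encoding_characters(self):
        with pytest.raises(Hl7EncodingError):
            parse_message(ORM_TEXT.replace("^~\\&", "^~\\"))

    def test_empty_control_id_rejected(self):
        with pytest.raises(Hl7StructuralError):
            parse_message(ORM_TEXT.replace("CTL001", ""))

    def test_profile_facility_mismatch(self, profiles):
        with pytest.raises(Hl7StructuralError, match="facility"):
            parse_message(ORM_TEXT.replace("MHTMC", "NOWHERE"), profiles["cerner"])


class TestSerialize:
    def test_round_trip_identity_on_generated_stream(self, profiles):
        """serialize∘parse is the identity on 100+ canonical messages."""
        cfg = fx.GeneratorConfig(n_patients=30, seed=11, n_orders=120)
        stream = fx.generate_order_stream(cfg)
        assert len(stream) >= 100
        for text in stream:
            assert serialize_message(parse_message(text)) == text

    def test_trailing_empty_fields_trimmed(self):
        seg = Segment("PID")
        seg.set(3, "MRN1")
        seg.set(8, "")
        msg = parse_message(ORM_TEXT)
        msg.segments[1] = seg
        assert "PID|||MRN1\r" in serialize_message(msg)

    def test_empty_message_rejected(self):
        msg = parse_message(ORM_TEXT)
        msg.segments = []
        with pytest.raises(Hl7StructuralError):
            serialize_message(msg)

    def test_escape_sequences_round_trip(self):
        raw = "wave & spike|sharp^slow~fast\\theta"
        assert unescape_text(escape_text(raw)) == raw
        assert "|" not in escape_text(raw)
        assert "^" not in escape_text(raw)

    def test_mllp_stream_framing(self):
        framed = "\x0b" + ORM_TEXT + "\x1c\x0d" + "\x0b" + ORM_TEXT + "\x1c\x0d"
        assert len(read_mllp_stream(framed)) == 2
        assert read_mllp_stream(ORM_TEXT) == [ORM_TEXT.strip("\r")]


class TestAck:
    def test_ack_echoes_control_id(self):
        msg = parse_message(ORM_TEXT)
        ack = build_ack(msg, "AA", control_id="A1", timestamp="20200315093100")
        msa = ack.segment("MSA")
        assert msa.get(1) == "AA"
        assert msa.get(2) == "CTL001"

    def test_ack_swaps_endpoints(self):
        ack = build_ack(parse_message(ORM_TEXT), "AA")
        assert ack.receiving_facility == "MHTMC"
        assert ack.sending_app == "EPICHART"

    def test_ack_second_segment_is_msa(self):
        ack = build_ack(parse_message(ORM_TEXT), "AE", text="missing mrn")
        text = serialize_message(ack)
        assert text.split("\r")[1].startswith("MSA|")

    def test_ack_reparses(self):
        ack = build_ack(parse_message(ORM_TEXT), "AR")
        reparsed = parse_message(serialize_message(ack))
        assert reparsed.segment("MSA").get(1) == "AR"

    def test_bad_code_rejected(self):
        with pytest.raises(ValidationError):
            build_ack(parse_message(ORM_TEXT), "OK")


class TestExtractOrder:
    def test_extracts_name_and_procedure(self, profiles):
        order = extract_order(parse_message(ORM_TEXT), profiles["cerner"])
        assert order.patient_name.family == "DOE"
        assert order.patient_name.given == "JANE"
        assert order.procedure_code == "EEG"
        assert order.procedure_text == "Electroencephalogram"
        assert order.source_vendor == "cerner"
        assert order.order_datetime == dt.datetime(2020, 3, 15, 9, 30)

    def test_missing_mrn_names_attribute(self, profiles):
        text = ORM_TEXT.replace("PID|||MRN00042|", "PID||||")
        with pytest.raises(ValidationError) as err:
            extract_order(parse_message(text), profiles["cerner"])
        assert "mrn" in err.value.details

    def test_cross_dialect_equivalence(self, profiles):
        """The same logical order rendered in either dialect extracts
        identically except for the vendor tag."""
        for seed in range(20):
            base = make_order(placer=f"PL{seed:04d}")
            records = {}
            for vendor, profile in profiles.items():
                msg = build_order(base, profile, control_id=f"C{seed}",
                                  timestamp="20200315093000")
                records[vendor] = extract_order(
                    parse_message(serialize_message(msg)), profile)
            a, c = records["allscripts"], records["cerner"]
            a.source_vendor = c.source_vendor = "x"
            assert a == c

    def test_wrong_message_type_rejected(self, profiles):
        ack = build_ack(parse_message(ORM_TEXT), "AA")
        with pytest.raises(StateError):
            extract_order(ack, profiles["cerner"])


def _finalized_report(service, attending, technician, fellow, order=None):
    report = service.create_report_from_order(order or make_order())
    service.submit_section(report, technician, "technician_findings",
                           SectionPayload("routine recording",
                                          {Category.EEG_ACTIVITY: ["EEGA110"]}))
    service.submit_section(report, fellow, "fellow_interpretation",
                           SectionPayload("left temporal sharp waves",
                                          {Category.EEG_ACTIVITY: ["EEGA120"]}))
    service.finalize_report(report, attending)
    return report


class TestBuildResult:
    def test_oru_echoes_order_ids(self, service, attending, technician, fellow, profiles):
        report = _finalized_report(service, attending, technician, fellow,
                                   make_order(placer="P1"))
        report.order.filler_id = "F1"
        oru = build_result(report, report.order, profiles["cerner"])
        obr = oru.segment("OBR")
        assert obr.get(2) == "P1"
        assert obr.get(3) == "F1"
        assert oru.message_type == "ORU^R01"

    def test_one_obx_per_populated_section(self, service, attending, technician,
                                           fellow, profiles):
        report = _finalized_report(service, attending, technician, fellow)
        report.sections["attending_review"] = SectionPayload("agree with fellow")
        oru = build_result(report, report.order, profiles["allscripts"])
        assert len(oru.all_segments("OBX")) == 3
        assert all(o.get(11) == "F" for o in oru.all_segments("OBX"))

    def test_amendment_marks_correction_status(self, service, attending, technician,
                                               fellow, profiles):
        report = _finalized_report(service, attending, technician, fellow)
        oru = build_result(report, report.order, profiles["cerner"], amended=True)
        assert all(o.get(11) == "C" for o in oru.all_segments("OBX"))

    def test_unfinalized_report_rejected(self, service, technician, profiles):
        report = service.create_report_from_order(make_order())
        service.submit_section(report, technician, "technician_findings",
                               SectionPayload("notes"))
        with pytest.raises(StateError):
            build_result(report, report.order, profiles["cerner"])

    def test_outbound_oru_reparses(self, service, attending, technician, fellow, profiles):
        report = _finalized_report(service, attending, technician, fellow)
        text = serialize_message(build_result(report, report.order, profiles["cerner"]))
        assert parse_message(text).message_type == "ORU^R01"


class TestBuildCharge:
    def _transmitted(self, service, attending, technician, fellow, profiles):
        report = _finalized_report(service, attending, technician, fellow)
        service.transmit_report(report, profiles["cerner"], actor=attending)
        service.register_ack(report, "AA")
        return report

    def test_one_ft1_per_procedure_code(self, service, attending, technician,
                                        fellow, profiles):
        report = self._transmitted(service, attending, technician, fellow, profiles)
        charge = ChargeRecord(["95816", "95957:26"], ["G40.209"], "att1",
                              dt.date(2020, 3, 16),
                              filed_at=dt.datetime(2020, 3, 17, 8, 0))
        dft = build_charge(report, charge, profiles["cerner"])
        assert dft.message_type == "DFT^P03"
        assert len(dft.all_segments("FT1")) == 2
        assert parse_message(serialize_message(dft)).has_segment("FT1")

    def test_billing_provider_is_attributed_physician(self, service, attending,
                                                      technician, fellow, profiles):
        report = self._transmitted(service, attending, technician, fellow, profiles)
        charge = ChargeRecord(["95816"], [], "someone-else", dt.date(2020, 3, 16),
                              filed_at=dt.datetime(2020, 3, 17, 8, 0))
        dft = build_charge(report, charge, profiles["cerner"])
        assert dft.segment("FT1").get(20) == report.attributed_physician

    def test_untransmitted_report_rejected(self, service, attending, technician,
                                           fellow, profiles):
        report = _finalized_report(service, attending, technician, fellow)
        charge = ChargeRecord(["95816"], [], "att1", dt.date(2020, 3, 16),
                              filed_at=dt.datetime(2020, 3, 17, 8, 0))
        with pytest.raises(StateError):
            build_charge(report, charge, profiles["cerner"])

    def test_future_service_date_rejected(self):
        with pytest.raises(ValidationError):
            ChargeRecord(["95816"], [], "att1", dt.date(2099, 1, 1))

    def test_empty_procedure_codes_rejected(self):
        with pytest.raises(ValidationError):
            ChargeRecord([], [], "att1", dt.date(2020, 1, 1),
                         filed_at=dt.datetime(2020, 1, 2))
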