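"""Faceted research-query layer.

Finalized reports are flattened into one record per patient carrying
demographics (date of birth, sex), diagnosis terms, other clinical-
characteristic terms, and medication names — the union over all of
that patient's reports. Cohorts are then built by conjunction of facet
filters; vocabulary filters may expand to a term's descendants, so a
query for a parent diagnosis also matches patients annotated only with
a more specific child term. Age is never stored: it is derived from
date of birth at query time against a reference date.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from epichart.errors import UnknownTermError, ValidationError
from epichart.ontology import Category, Ontology, descendants_of
from epichart.workflow import Report, ReportState


@dataclass
class PatientRecord:
    mrn: str
    dob: dt.date | None
    sex: str
    last_report_date: dt.date | None
    diagnosis_terms: set[str] = field(default_factory=set)
    characteristic_terms: set[str] = field(default_factory=set)
    medications: set[str] = field(default_factory=set)

    def age_on(self, reference: dt.date) -> int | None:
        if self.dob is None:
            return None
        years = reference.year - self.dob.year
        if (reference.month, reference.day) < (self.dob.month, self.dob.day):
            years -= 1
        return years


@dataclass
class PatientIndex:
    """One record per MRN; the queryable research view of the registry."""

    records: dict[str, PatientRecord]
    built_at: dt.date

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, mrn: str) -> bool:
        return mrn in self.records


class FilterKind(enum.Enum):
    AGE_RANGE = "age_range"
    SEX = "sex"
    DIAGNOSIS_TERM = "diagnosis_term"
    CHARACTERISTIC_TERM = "characteristic_term"
    MEDICATION = "medication"


@dataclass(frozen=True)
class FacetFilter:
    """One facet constraint; a cohort query is a conjunction of these.

    ``value`` is an ``(lo, hi)`` year pair for AGE_RANGE (either end
    may be None), a term id for the vocabulary kinds (with
    ``expand_descendants`` widening the match to the whole subtree),
    and a case-insensitive name for SEX and MEDICATION.
    """

    kind: FilterKind
    value: object
    expand_descendants: bool = False

    def __post_init__(self) -> None:
        if self.kind is FilterKind.AGE_RANGE:
            ok = (isinstance(self.value, tuple) and len(self.value) == 2
                  and all(v is None or isinstance(v, int) for v in self.value))
            if not ok:
                raise ValidationError("age_range value must be a (lo, hi) pair of ints/None")
        elif not isinstance(self.value, str) or not self.value:
            raise ValidationError(f"{self.kind.value} value must be a non-empty string")
        if self.expand_descendants and self.kind not in (
                FilterKind.DIAGNOSIS_TERM, FilterKind.CHARACTERISTIC_TERM):
            raise ValidationError("descendant expansion applies only to term filters")


def build_index(reports: Iterable[Report], ont: Ontology) -> PatientIndex:
    """Fold finalized reports into per-patient records.

    Reports not yet finalized are rejected; so is any structured term
    that the vocabulary does not know, naming the offending report.
    Diagnosis terms are those in the epileptic-diagnosis category;
    every other category lands in clinical characteristics.
    """
    records: dict[str, PatientRecord] = {}
    for report in reports:
        if report.state < ReportState.FINALIZED:
            raise ValidationError(
                f"report {report.report_id} is {report.state.name}; only "
                "finalized reports are indexed")
        rec = records.get(report.patient_mrn)
        if rec is None:
            rec = PatientRecord(
                mrn=report.patient_mrn,
                dob=report.order.dob,
                sex=report.order.sex,
                last_report_date=None,
            )
            records[report.patient_mrn] = rec
        rdate = report.finalized_at.date() if report.finalized_at else None
        if rdate and (rec.last_report_date is None or rdate > rec.last_report_date):
            rec.last_report_date = rdate
        for _, payload in report.populated_sections():
            for tid in payload.term_ids():
                if tid not in ont:
                    raise ValidationError(
                        f"report {report.report_id} carries unknown term {tid!r}")
                if ont.terms[tid].category is Category.EPILEPTIC_DIAGNOSIS:
                    rec.diagnosis_terms.add(tid)
                else:
                    rec.characteristic_terms.add(tid)
            rec.medications.update(m for m in payload.medications if m)
    return PatientIndex(records=records, built_at=dt.date.today())


def _term_matches(patient_terms: set[str], flt: FacetFilter, ont: Ontology) -> bool:
    term = flt.value
    if term not in ont:
        raise UnknownTermError(f"filter references unknown term {term!r}")
    wanted = {term}
    if flt.expand_descendants:
        wanted |= descendants_of(ont, term)
    return bool(patient_terms & wanted)


def build_cohort(
    index: PatientIndex,
    filters: Sequence[FacetFilter],
    ont: Ontology,
    reference_date: dt.date | None = None,
) -> set[str]:
    """MRNs of patients matching every filter (empty filter list ⇒ all).

    ``reference_date`` anchors age computation; it defaults to the
    index build date so repeated queries over one index agree.
    """
    ref = reference_date or index.built_at
    out: set[str] = set()
    for mrn, rec in index.records.items():
        if all(_matches(rec, f, ont, ref) for f in filters):
            out.add(mrn)
    return out


def _matches(rec: PatientRecord, flt: FacetFilter, ont: Ontology, ref: dt.date) -> bool:
    if flt.kind is FilterKind.AGE_RANGE:
        lo, hi = flt.value
        age = rec.age_on(ref)
        if age is None:
            return False
        return (lo is None or age >= lo) and (hi is None or age <= hi)
    if flt.kind is FilterKind.SEX:
        return rec.sex.upper() == str(flt.value).upper()
    if flt.kind is FilterKind.DIAGNOSIS_TERM:
        return _term_matches(rec.diagnosis_terms, flt, ont)
    if flt.kind is FilterKind.CHARACTERISTIC_TERM:
        return _term_matches(rec.characteristic_terms, flt, ont)
    if flt.kind is FilterKind.MEDICATION:
        return str(flt.value).lower() in {m.lower() for m in rec.medications}
    raise ValidationError(f"unknown filter kind {flt.kind}")  # pragma: no cover


EXPORT_FIELDS = ("mrn", "dob", "sex", "age", "diagnosis_terms",
                 "characteristic_terms", "medications")


def export_cohort(
    index: PatientIndex,
    cohort: Iterable[str],
    fields: Sequence[str] = EXPORT_FIELDS,
    reference_date: dt.date | None = None,
    deidentify: bool = False,
) -> list[dict[str, str]]:
    """Tabular rows for a cohort, one per patient in MRN order.

    ``deidentify=True`` drops the mrn column regardless of ``fields``.
    Set-valued columns are serialized as ``;``-joined sorted values.
    """
    unknown = [f for f in fields if f not in EXPORT_FIELDS]
    if unknown:
        raise ValidationError(f"unknown export fields {unknown}; valid: {EXPORT_FIELDS}")
    mrns = sorted(cohort)
    missing = [m for m in mrns if m not in index]
    if missing:
        raise ValidationError(f"cohort MRNs absent from index: {missing}")
    ref = reference_date or index.built_at
    out_fields = [f for f in fields if not (deidentify and f == "mrn")]
    rows = []
    for mrn in mrns:
        rec = index.records[mrn]
        values = {
            "mrn": rec.mrn,
            "dob": rec.dob.isoformat() if rec.dob else "",
            "sex": rec.sex,
            "age": str(rec.age_on(ref)) if rec.age_on(ref) is not None else "",
            "diagnosis_terms": ";".join(sorted(rec.diagnosis_terms)),
            "characteristic_terms": ";".join(sorted(rec.characteristic_terms)),
            "medications": ";".join(sorted(rec.medications)),
        }
        rows.append({f: values[f] for f in out_fields})
    return rows


def export_csv(rows: list[dict[str, str]],
               fields: Sequence[str] | None = None) -> str:
    """Render export rows to CSV (header always written)."""
    names = list(fields) if fields else (list(rows[0]) if rows else list(EXPORT_FIELDS))
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=names)
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def import_index(csv_text: str) -> PatientIndex:
    """Rebuild a :class:`PatientIndex` from a full-field cohort export.

    Inverse of :func:`export_cohort` with the default field list, so a
    cohort can be exported, shared and re-queried.
    """
    records: dict[str, PatientRecord] = {}
    for row in csv.DictReader(io.StringIO(csv_text)):
        if "mrn" not in row or row["mrn"] is None:
            raise ValidationError("import requires an mrn column")
        rec = PatientRecord(
            mrn=row["mrn"],
            dob=dt.date.fromisoformat(row["dob"]) if row.get("dob") else None,
            sex=row.get("sex", ""),
            last_report_date=None,
            diagnosis_terms=set(filter(None, row.get("diagnosis_terms", "").split(";"))),
            characteristic_terms=set(filter(None, row.get("characteristic_terms", "").split(";"))),
            medications=set(filter(None, row.get("medications", "").split(";"))),
        )
        records[rec.mrn] = rec
    return PatientIndex(records=records, built_at=dt.date.today())
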