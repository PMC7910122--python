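"""Seeded synthetic data for every subsystem.

Nothing here is clinical truth: generators produce structurally valid
artifacts — HL7 order streams in both vendor dialects, a completed-
report ledger mirroring the deployment's published per-type usage
counts, journey registries, and a small six-category vocabulary — so
the whole engine is exercisable with no external data. All generators
are pure functions of their configuration and seed.

The mini ontology is a synthetic stand-in for a real epilepsy and
seizure ontology export: its six category roots and hierarchy shape
are faithful to how such a vocabulary is organised, but the term list
is illustrative and non-authoritative (a real export exceeds 600
terms).
"""

from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass, field

from epichart.errors import ValidationError
from epichart.hl7 import OrderRecord, PersonName, serialize_message
from epichart.hl7.builders import build_order
from epichart.hl7.dialect import allscripts_profile, cerner_profile
from epichart.dashboard import LedgerEntry
from epichart.tracker import JourneyStep, PatientJourney, StepStatus
from epichart.workflow import ReportTypeCode

#: Report-type mix defaulting to the deployed system's observed shares
#: (15,417 : 1369 : 2635 over 19,421 production reports).
DEFAULT_TYPE_MIX: dict[ReportTypeCode, float] = {
    ReportTypeCode.EEG: 15417 / 19421,
    ReportTypeCode.EMU_PHASE: 1369 / 19421,
    ReportTypeCode.EMU_DAILY: 2635 / 19421,
    ReportTypeCode.EVOKED_POTENTIALS: 0.0,
}

_PROCEDURE_FOR_TYPE = {
    ReportTypeCode.EEG: ("EEG", "Electroencephalogram"),
    ReportTypeCode.EMU_PHASE: ("EMUPH", "EMU Phase Report"),
    ReportTypeCode.EMU_DAILY: ("EMUD", "EMU Daily Report"),
    ReportTypeCode.EVOKED_POTENTIALS: ("EP", "Evoked Potentials"),
}

_FAMILY_NAMES = [
    "ALVAREZ", "BROOKS", "CHEN", "DAVIS", "ERICKSON", "FLORES", "GARCIA",
    "HUANG", "IBRAHIM", "JOHNSON", "KOWALSKI", "LEE", "MARTIN", "NGUYEN",
    "OKAFOR", "PATEL", "QUINN", "ROSSI", "SINGH", "TANAKA",
]
_GIVEN_NAMES = [
    "ALEX", "BLAKE", "CASEY", "DANA", "ELLIS", "FRAN", "GALE", "HARPER",
    "IRIS", "JORDAN", "KAI", "LEE", "MORGAN", "NOOR", "OWEN", "PARKER",
    "QUINN", "RILEY", "SAM", "TAYLOR",
]
_PROVIDERS = ["DRADAMS", "DRBAKER", "DRCRUZ", "DRDIAZ", "DREVANS", "DRFOX"]


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic generators.

    ``vendor_mix`` is the proportion of orders rendered in the
    allscripts dialect (the rest are cerner); ``report_type_mix``
    defaults to the deployed per-type shares.
    """

    n_patients: int = 50
    seed: int = 7
    date_range: tuple[dt.date, dt.date] = (dt.date(2019, 2, 18), dt.date(2020, 9, 21))
    vendor_mix: float = 0.5
    report_type_mix: dict[ReportTypeCode, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    n_orders: int | None = None  # default: 2 × n_patients

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be ≥ 1")
        if not 0.0 <= self.vendor_mix <= 1.0:
            raise ValidationError("vendor_mix must lie in [0, 1]")
        if abs(sum(self.report_type_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("report_type_mix proportions must sum to 1")
        if self.date_range[0] > self.date_range[1]:
            raise ValidationError("date_range start must not exceed end")

    @property
    def order_count(self) -> int:
        return self.n_orders if self.n_orders is not None else 2 * self.n_patients


def _mrn(i: int) -> str:
    return f"MRN{i:05d}"


def _random_datetime(rng: random.Random, lo: dt.date, hi: dt.date) -> dt.datetime:
    days = (hi - lo).days
    return dt.datetime.combine(lo + dt.timedelta(days=rng.randint(0, days)),
                               dt.time(rng.randint(7, 18), rng.randint(0, 59)))


def _pick_type(rng: random.Random, mix: dict[ReportTypeCode, float]) -> ReportTypeCode:
    x = rng.random()
    acc = 0.0
    for code, p in mix.items():
        acc += p
        if x < acc:
            return code
    return next(iter(mix))


def generate_orders(cfg: GeneratorConfig) -> list[OrderRecord]:
    """Logical order records (before dialect rendering)."""
    rng = random.Random(cfg.seed)
    lo, hi = cfg.date_range
    orders = []
    for i in range(cfg.order_count):
        patient = rng.randrange(cfg.n_patients)
        vendor = "allscripts" if rng.random() < cfg.vendor_mix else "cerner"
        rtype = _pick_type(rng, cfg.report_type_mix)
        code, text = _PROCEDURE_FOR_TYPE[rtype]
        orders.append(OrderRecord(
            mrn=_mrn(patient),
            patient_name=PersonName(
                _FAMILY_NAMES[patient % len(_FAMILY_NAMES)],
                _GIVEN_NAMES[(patient * 7 + 3) % len(_GIVEN_NAMES)]),
            dob=dt.date(1950 + (patient * 13) % 60, 1 + (patient * 5) % 12,
                        1 + (patient * 11) % 28),
            sex="F" if patient % 2 else "M",
            placer_id=f"PL{cfg.seed:03d}{i:05d}",
            filler_id=f"FL{cfg.seed:03d}{i:05d}",
            procedure_code=code,
            procedure_text=text,
            ordering_provider=rng.choice(_PROVIDERS),
            order_datetime=_random_datetime(rng, lo, hi),
            source_vendor=vendor,
        ))
    return orders


def generate_order_stream(cfg: GeneratorConfig) -> list[str]:
    """Raw ORM^O01 texts, each rendered in its order's vendor dialect.

    Deterministic for a fixed config; every message parses cleanly
    under the matching profile and round-trips byte-for-byte.
    """
    profiles = {"allscripts": allscripts_profile(), "cerner": cerner_profile()}
    out = []
    for i, order in enumerate(generate_orders(cfg)):
        profile = profiles[order.source_vendor]
        msg = build_order(
            order, profile,
            control_id=f"CTL{cfg.seed:03d}{i:05d}",
            timestamp=order.order_datetime.strftime("%Y%m%d%H%M%S"),
        )
        out.append(serialize_message(msg))
    return out


# --- usage ledger ------------------------------------------------------

#: Published per-type usage of the deployed system as of 2020-09-21:
#: (production start, completed reports, distinct patients).
USAGE_TABLE: dict[ReportTypeCode, tuple[dt.date | None, int, int]] = {
    ReportTypeCode.EEG: (dt.date(2019, 2, 18), 15417, 6382),
    ReportTypeCode.EMU_PHASE: (dt.date(2019, 7, 1), 1369, 1053),
    ReportTypeCode.EMU_DAILY: (dt.date(2019, 11, 15), 2635, 312),
    ReportTypeCode.EVOKED_POTENTIALS: (None, 0, 0),
}

USAGE_END_DATE = dt.date(2020, 9, 21)


def usage_ledger(seed: int = 0) -> list[LedgerEntry]:
    """Completed-report ledger matching the published per-type usage counts.

    Per type, the number of entries and the number of distinct MRNs
    equal the published figures; completion dates are uniform between
    the type's production start and the census date. Dates and MRN
    assignments are synthetic (only the counts are contractual), and
    per-type patient pools are disjoint, so the ledger's overall
    distinct-patient count is the sum of the per-type figures, not the
    deployment's cross-type-overlapping unique-patient total.
    """
    rng = random.Random(seed)
    ledger: list[LedgerEntry] = []
    pool_offset = 0
    for rtype, (start, n_reports, n_patients) in USAGE_TABLE.items():
        if n_reports == 0:
            continue
        mrns = [_mrn(pool_offset + i) for i in range(n_patients)]
        pool_offset += n_patients
        days = (USAGE_END_DATE - start).days
        # every patient appears at least once; the rest are drawn uniformly
        assignments = mrns + [rng.choice(mrns) for _ in range(n_reports - n_patients)]
        rng.shuffle(assignments)
        for mrn in assignments:
            completed = start + dt.timedelta(days=rng.randint(0, days))
            billed = completed if rng.random() < 0.9 else None
            ledger.append(LedgerEntry(
                report_type=rtype,
                patient_mrn=mrn,
                completed_date=completed,
                documented_date=completed,
                billed_date=billed,
                physician=rng.choice(_PROVIDERS),
            ))
    return ledger


# --- journeys ----------------------------------------------------------

_STATUS_WEIGHTS = [(StepStatus.NOT_STARTED, 0.4), (StepStatus.ORDERED, 0.2),
                   (StepStatus.SCHEDULED, 0.15), (StepStatus.COMPLETE, 0.25)]


def generate_journeys(cfg: GeneratorConfig) -> list[PatientJourney]:
    """Seeded journey registry: random step statuses with in-range dates."""
    rng = random.Random(cfg.seed + 1)  # decouple from the order stream
    lo, hi = cfg.date_range
    days = (hi - lo).days
    journeys = []
    for i in range(cfg.n_patients):
        statuses: dict[JourneyStep, tuple[StepStatus, dt.date | None]] = {}
        for step in JourneyStep:
            x = rng.random()
            acc = 0.0
            status = StepStatus.NOT_STARTED
            for s, w in _STATUS_WEIGHTS:
                acc += w
                if x < acc:
                    status = s
                    break
            date = (lo + dt.timedelta(days=rng.randint(0, days))
                    if status is not StepStatus.NOT_STARTED else None)
            statuses[step] = (status, date)
        journeys.append(PatientJourney(
            patient_mrn=_mrn(i),
            patient_name=(f"{_FAMILY_NAMES[i % len(_FAMILY_NAMES)]}, "
                          f"{_GIVEN_NAMES[(i * 7 + 3) % len(_GIVEN_NAMES)]}"),
            statuses=statuses,
        ))
    return journeys


# --- mini ontology -----------------------------------------------------


def mini_ontology_rows() -> list[tuple[str, str, str | None, str]]:
    """Synthetic ~60-term vocabulary: six category roots, depth ≥ 3.

    Rows are (term_id, label, parent_id, category) ready for
    :func:`epichart.ontology.load_ontology`.
    """
    dx, sem, ez, lat, eeg, et = ("epileptic_diagnosis", "semiology",
                                 "epileptogenic_zone", "lateralizing_sign",
                                 "eeg_activity", "etiology")
    return [
        # epileptic diagnoses (depth-4 chain under focal → temporal)
        ("DX000", "Epileptic diagnosis", None, dx),
        ("DX100", "Focal epilepsy", "DX000", dx),
        ("DX110", "Temporal lobe epilepsy", "DX100", dx),
        ("DX111", "Mesial temporal lobe epilepsy", "DX110", dx),
        ("DX112", "Lateral temporal lobe epilepsy", "DX110", dx),
        ("DX120", "Frontal lobe epilepsy", "DX100", dx),
        ("DX130", "Parietal lobe epilepsy", "DX100", dx),
        ("DX140", "Occipital lobe epilepsy", "DX100", dx),
        ("DX200", "Generalized epilepsy", "DX000", dx),
        ("DX210", "Childhood absence epilepsy", "DX200", dx),
        ("DX220", "Juvenile myoclonic epilepsy", "DX200", dx),
        ("DX300", "Combined generalized and focal epilepsy", "DX000", dx),
        # semiologies
        ("SEM000", "Semiology", None, sem),
        ("SEM100", "Aura", "SEM000", sem),
        ("SEM110", "Epigastric aura", "SEM100", sem),
        ("SEM120", "Olfactory aura", "SEM100", sem),
        ("SEM200", "Motor semiology", "SEM000", sem),
        ("SEM210", "Tonic activity", "SEM200", sem),
        ("SEM220", "Clonic activity", "SEM200", sem),
        ("SEM230", "Automatisms", "SEM200", sem),
        ("SEM300", "Non-motor semiology", "SEM000", sem),
        ("SEM310", "Behavior arrest", "SEM300", sem),
        ("SEM320", "Dialeptic seizure", "SEM300", sem),
        # epileptogenic zones
        ("EZ000", "Epileptogenic zone", None, ez),
        ("EZ100", "Temporal epileptogenic zone", "EZ000", ez),
        ("EZ110", "Mesial temporal epileptogenic zone", "EZ100", ez),
        ("EZ200", "Frontal epileptogenic zone", "EZ000", ez),
        ("EZ300", "Insular epileptogenic zone", "EZ000", ez),
        ("EZ400", "Parietal epileptogenic zone", "EZ000", ez),
        # lateralizing signs
        ("LAT000", "Lateralizing sign", None, lat),
        ("LAT100", "Dystonic posturing", "LAT000", lat),
        ("LAT200", "Head version", "LAT000", lat),
        ("LAT300", "Postictal nose wiping", "LAT000", lat),
        ("LAT400", "Ictal speech", "LAT000", lat),
        ("LAT500", "Todd paresis", "LAT000", lat),
        # EEG activities
        ("EEGA000", "EEG activity", None, eeg),
        ("EEGA100", "Interictal activity", "EEGA000", eeg),
        ("EEGA110", "Spike", "EEGA100", eeg),
        ("EEGA120", "Sharp wave", "EEGA100", eeg),
        ("EEGA130", "Spike-and-wave complex", "EEGA100", eeg),
        ("EEGA200", "Ictal activity", "EEGA000", eeg),
        ("EEGA210", "Rhythmic theta", "EEGA200", eeg),
        ("EEGA220", "Low-voltage fast activity", "EEGA200", eeg),
        ("EEGA300", "Slowing", "EEGA000", eeg),
        ("EEGA310", "Focal slowing", "EEGA300", eeg),
        ("EEGA320", "Generalized slowing", "EEGA300", eeg),
        # etiologies
        ("ET000", "Etiology", None, et),
        ("ET100", "Structural etiology", "ET000", et),
        ("ET110", "Hippocampal sclerosis", "ET100", et),
        ("ET120", "Focal cortical dysplasia", "ET100", et),
        ("ET130", "Tumor", "ET100", et),
        ("ET200", "Genetic etiology", "ET000", et),
        ("ET300", "Infectious etiology", "ET000", et),
        ("ET400", "Metabolic etiology", "ET000", et),
        ("ET500", "Immune etiology", "ET000", et),
        ("ET600", "Unknown etiology", "ET000", et),
    ]


def mini_ontology():
    """Loaded and validated mini vocabulary."""
    from epichart.ontology import load_ontology

    return load_ontology(mini_ontology_rows())
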