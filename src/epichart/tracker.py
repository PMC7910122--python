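"""Surgical-candidate journey tracker.

Patients working up toward epilepsy surgery pass through up to 14
clinical steps, from epilepsy-monitoring-unit admission through
intracranial investigation and surgery to postoperative evaluation.
The tracker keeps one status per step per patient (not started /
ordered / scheduled / complete, colour-coded in the UI layer), lets
nurse navigators record bottleneck comments broadcast to all teams,
and answers conjunctive status searches ("patient management complete
AND stereo-EEG not started") over the whole registry.

Steps carry no enforced inter-step ordering — real journeys branch and
skip — but a COMPLETE status cannot silently regress; reverting it
requires an explicit audited override.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable

from epichart.errors import StateError, ValidationError
from epichart.rbac import AccessPolicy, User, require

#: The default journey: 14 steps of the surgical work-up, in the order a
#: typical candidate encounters them. Installations may reconfigure.
class JourneyStep(enum.Enum):
    EMU_ADMISSION = "emu_admission"
    EMU_DISCHARGE = "emu_discharge"
    PET = "pet"
    ICTAL_SPECT = "ictal_spect"
    MEG = "meg"
    NEUROPSYCHOLOGY = "neuropsychology"
    FMRI = "fmri"
    WADA = "wada"
    PATIENT_MANAGEMENT = "patient_management"
    SEEG = "seeg"
    SURGERY = "surgery"
    POSTOP_EEG = "postop_eeg"
    POSTOP_MRI = "postop_mri"
    POSTOP_NEUROPSYCH = "postop_neuropsych"


class StepStatus(enum.Enum):
    """Completion status of one step; ``color`` is display metadata only."""

    NOT_STARTED = "not_started"
    ORDERED = "ordered"
    SCHEDULED = "scheduled"
    COMPLETE = "complete"

    @property
    def color(self) -> str:
        return {"not_started": "red", "ordered": "blue",
                "scheduled": "yellow", "complete": "green"}[self.value]


@dataclass(frozen=True)
class Comment:
    author: str
    timestamp: dt.datetime
    text: str


@dataclass
class PatientJourney:
    """One patient's status vector over all journey steps."""

    patient_mrn: str
    patient_name: str
    statuses: dict[JourneyStep, tuple[StepStatus, dt.date | None]] = field(default_factory=dict)
    comments: list[Comment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for step in JourneyStep:
            self.statuses.setdefault(step, (StepStatus.NOT_STARTED, None))

    def status(self, step: JourneyStep) -> StepStatus:
        return self.statuses[step][0]

    def status_date(self, step: JourneyStep) -> dt.date | None:
        return self.statuses[step][1]


@dataclass(frozen=True)
class JourneyQuery:
    """Conjunctive search: all given constraints must hold.

    The empty query matches every journey. Name matching is a
    case-insensitive substring test; MRN is exact; each step constraint
    is an exact status match.
    """

    name_substring: str | None = None
    mrn: str | None = None
    step_constraints: dict[JourneyStep, StepStatus] = field(default_factory=dict)

    def matches(self, journey: PatientJourney) -> bool:
        if self.mrn is not None and journey.patient_mrn != self.mrn:
            return False
        if (self.name_substring is not None
                and self.name_substring.lower() not in journey.patient_name.lower()):
            return False
        return all(journey.status(step) == status
                   for step, status in self.step_constraints.items())


class JourneyRegistry:
    """Journeys keyed by MRN, with the tracker's update/search/comment ops."""

    def __init__(self, policy: AccessPolicy, clock=dt.datetime.now,
                 auto_order_on_ingest: bool = False):
        self.policy = policy
        self.clock = clock
        self.journeys: dict[str, PatientJourney] = {}
        self.notifications: list[tuple[str, str, dt.datetime]] = []
        #: optional hook: mark a step ORDERED when a matching order arrives
        self.auto_order_on_ingest = auto_order_on_ingest

    def add(self, journey: PatientJourney) -> PatientJourney:
        if journey.patient_mrn in self.journeys:
            raise ValidationError(f"journey for MRN {journey.patient_mrn} already exists")
        self.journeys[journey.patient_mrn] = journey
        return journey

    def get(self, mrn: str) -> PatientJourney:
        try:
            return self.journeys[mrn]
        except KeyError:
            raise ValidationError(f"no journey for MRN {mrn!r}") from None

    def set_step_status(
        self,
        journey: PatientJourney,
        step: JourneyStep,
        status: StepStatus,
        status_date: dt.date | None,
        actor: User,
        override: bool = False,
    ) -> PatientJourney:
        """Update one step; only navigators (or admin) may drive the tracker.

        Any status other than NOT_STARTED needs a date. Regressing a
        COMPLETE step requires ``override=True`` and leaves a comment
        recording who overrode it.
        """
        require(self.policy, actor, "update_status", "tracker")
        if status is not StepStatus.NOT_STARTED and status_date is None:
            raise ValidationError(f"status {status.value} requires a date")
        if status is StepStatus.NOT_STARTED and status_date is not None:
            raise ValidationError("NOT_STARTED carries no date")
        current = journey.status(step)
        if current is StepStatus.COMPLETE and status is not StepStatus.COMPLETE:
            if not override:
                raise StateError(
                    f"step {step.value} is COMPLETE; regression to "
                    f"{status.value} requires an explicit override")
            journey.comments.append(Comment(
                actor.user_id, self.clock(),
                f"[override] {step.value} regressed from complete to {status.value}"))
        journey.statuses[step] = (status, status_date)
        return journey

    def add_comment(self, journey: PatientJourney, actor: User, text: str) -> PatientJourney:
        """Append a bottleneck comment and notify all clinical teams."""
        require(self.policy, actor, "comment", "tracker")
        if not text.strip():
            raise ValidationError("comment text must be non-empty")
        now = self.clock()
        journey.comments.append(Comment(actor.user_id, now, text))
        self.notifications.append(
            ("all_teams", f"tracker comment on {journey.patient_mrn}: {text}", now))
        return journey

    def search(self, query: JourneyQuery) -> list[PatientJourney]:
        """All journeys satisfying every constraint, ordered by MRN."""
        return [self.journeys[mrn] for mrn in sorted(self.journeys)
                if query.matches(self.journeys[mrn])]

    def order_received_hook(self, mrn: str, step: JourneyStep, order_date: dt.date,
                            actor: User) -> None:
        """Optional ingest hook: mark a step ORDERED when its order arrives.

        Disabled by default (``auto_order_on_ingest=False``); when
        enabled, it never downgrades a step already past ORDERED.
        """
        if not self.auto_order_on_ingest or mrn not in self.journeys:
            return
        journey = self.journeys[mrn]
        if journey.status(step) is StepStatus.NOT_STARTED:
            self.set_step_status(journey, step, StepStatus.ORDERED, order_date, actor)


def journeys_to_jsonl(journeys: Iterable[PatientJourney]) -> str:
    """Serialize journeys to JSON-lines (one journey per line)."""
    import json

    lines = []
    for j in sorted(journeys, key=lambda x: x.patient_mrn):
        lines.append(json.dumps({
            "mrn": j.patient_mrn,
            "name": j.patient_name,
            "statuses": {step.value: [status.value,
                                      date.isoformat() if date else None]
                         for step, (status, date) in j.statuses.items()},
            "comments": [[c.author, c.timestamp.isoformat(), c.text]
                         for c in j.comments],
        }))
    return "\n".join(lines) + ("\n" if lines else "")


def journeys_from_jsonl(text: str) -> list[PatientJourney]:
    """Inverse of :func:`journeys_to_jsonl`."""
    import json

    journeys = []
    for line in text.splitlines():
        if not line.strip():
            continue
        data = json.loads(line)
        statuses = {
            JourneyStep(step): (StepStatus(status),
                                dt.date.fromisoformat(date) if date else None)
            for step, (status, date) in data.get("statuses", {}).items()
        }
        journeys.append(PatientJourney(
            patient_mrn=data["mrn"],
            patient_name=data.get("name", ""),
            statuses=statuses,
            comments=[Comment(a, dt.datetime.fromisoformat(ts), txt)
                      for a, ts, txt in data.get("comments", [])],
        ))
    return journeys


def grid_rows(journeys: Iterable[PatientJourney]) -> list[dict[str, str]]:
    """Flatten journeys to rows for CSV export of the tracker grid."""
    rows = []
    for j in sorted(journeys, key=lambda x: x.patient_mrn):
        row = {"mrn": j.patient_mrn, "name": j.patient_name}
        for step in JourneyStep:
            status, date = j.statuses[step]
            row[step.value] = status.value + (f":{date.isoformat()}" if date else "")
        rows.append(row)
    return rows
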