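"""Physician-dashboard analytics and service scheduling.

The dashboard's four surfaces map onto backend operations: the reports
tab is :meth:`~epichart.workflow.ReportService.outstanding_reports`,
the billing tab is :meth:`~epichart.workflow.ReportService.file_billing`,
the statistics tab is :func:`report_statistics` (reports by calendar
month and study type), and the schedule tab is the year-long
:class:`ServiceSchedule` with physician-to-physician swap requests.
The schedule also powers automatic attribution: a finalized report
belongs to whoever was on service for its study type on the
finalization date.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from epichart.errors import ConsistencyError, CoverageError, StateError, ValidationError
from epichart.workflow import Report, ReportTypeCode

#: Default service lines: one per report study type.
DEFAULT_SERVICE_LINES = tuple(code.value for code in ReportTypeCode)


@dataclass(frozen=True)
class LedgerEntry:
    """One completed report as the statistics tab sees it.

    ``completed_date`` is the finalization date (the canonical
    counter); ``documented_date`` and ``billed_date`` are optional
    parallel events.
    """

    report_type: ReportTypeCode
    patient_mrn: str
    completed_date: dt.date
    documented_date: dt.date | None = None
    billed_date: dt.date | None = None
    physician: str = ""


@dataclass
class ReportStats:
    """Counts by (month, study type), with per-type and grand totals.

    ``completed`` drives the totals; ``documented`` and ``billed`` are
    parallel maps over their own event dates.
    """

    completed: dict[tuple[str, ReportTypeCode], int]
    documented: dict[tuple[str, ReportTypeCode], int]
    billed: dict[tuple[str, ReportTypeCode], int]
    totals_by_type: dict[ReportTypeCode, int]
    grand_total: int

    def __post_init__(self) -> None:
        if self.grand_total != sum(self.completed.values()):
            raise ConsistencyError("grand total does not equal the sum of cells")
        if self.totals_by_type != self._recount():
            raise ConsistencyError("per-type totals do not match cells")

    def _recount(self) -> dict[ReportTypeCode, int]:
        out: dict[ReportTypeCode, int] = {}
        for (_, rtype), n in self.completed.items():
            out[rtype] = out.get(rtype, 0) + n
        return out


def report_statistics(
    ledger: Iterable[LedgerEntry],
    interval: tuple[dt.date, dt.date],
) -> ReportStats:
    """Aggregate a report ledger into month × study-type counts.

    ``interval`` is inclusive on both ends; entries outside it are
    ignored per event (an entry completed inside but billed outside
    counts as completed only). Months are labelled ``YYYY-MM``.
    """
    start, end = interval
    if start > end:
        raise ValidationError(f"reversed interval {start}..{end}")

    entries = list(ledger)

    def bucket(dates: list[tuple[dt.date | None, ReportTypeCode]]):
        rows = [(d, t.value) for d, t in dates if d is not None and start <= d <= end]
        if not rows:
            return {}
        df = pd.DataFrame(rows, columns=["date", "type"])
        df["month"] = df["date"].map(lambda d: f"{d.year:04d}-{d.month:02d}")
        grouped = df.groupby(["month", "type"], sort=True).size()
        return {(month, ReportTypeCode(tval)): int(n)
                for (month, tval), n in grouped.items()}

    completed = bucket([(e.completed_date, e.report_type) for e in entries])
    documented = bucket([(e.documented_date, e.report_type) for e in entries])
    billed = bucket([(e.billed_date, e.report_type) for e in entries])
    totals: dict[ReportTypeCode, int] = {}
    for (_, rtype), n in completed.items():
        totals[rtype] = totals.get(rtype, 0) + n
    return ReportStats(completed, documented, billed, totals, sum(completed.values()))


def stats_to_csv(stats: ReportStats) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["month", "report_type", "completed", "documented", "billed"])
    keys = sorted(set(stats.completed) | set(stats.documented) | set(stats.billed),
                  key=lambda k: (k[0], k[1].value))
    for month, rtype in keys:
        writer.writerow([
            month, rtype.value,
            stats.completed.get((month, rtype), 0),
            stats.documented.get((month, rtype), 0),
            stats.billed.get((month, rtype), 0),
        ])
    return buf.getvalue()


def ledger_to_csv(ledger: Iterable[LedgerEntry]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["report_type", "patient_mrn", "completed_date",
                     "documented_date", "billed_date", "physician"])
    for e in ledger:
        writer.writerow([
            e.report_type.value, e.patient_mrn, e.completed_date.isoformat(),
            e.documented_date.isoformat() if e.documented_date else "",
            e.billed_date.isoformat() if e.billed_date else "",
            e.physician,
        ])
    return buf.getvalue()


def ledger_from_csv(text: str) -> list[LedgerEntry]:
    out = []
    for row in csv.DictReader(io.StringIO(text)):
        out.append(LedgerEntry(
            report_type=ReportTypeCode(row["report_type"]),
            patient_mrn=row["patient_mrn"],
            completed_date=dt.date.fromisoformat(row["completed_date"]),
            documented_date=(dt.date.fromisoformat(row["documented_date"])
                             if row.get("documented_date") else None),
            billed_date=(dt.date.fromisoformat(row["billed_date"])
                         if row.get("billed_date") else None),
            physician=row.get("physician", ""),
        ))
    return out


# --- service schedule --------------------------------------------------


class SwapState(enum.Enum):
    PENDING = "pending"
    ACCEPTED = "accepted"
    DECLINED = "declined"


@dataclass
class SwapRequest:
    requester: str
    counterparty: str
    service_line: str
    dates_a: frozenset[dt.date]  # requester's dates offered
    dates_b: frozenset[dt.date]  # counterparty's dates offered
    state: SwapState = SwapState.PENDING
    request_id: str = ""


@dataclass
class ServiceSchedule:
    """Year calendar of (date, service line) → physician assignments."""

    year: int
    assignments: dict[tuple[dt.date, str], str]
    service_lines: tuple[str, ...] = DEFAULT_SERVICE_LINES
    swap_requests: list[SwapRequest] = field(default_factory=list)
    _swap_ids: itertools.count = field(default_factory=lambda: itertools.count(1))

    def __post_init__(self) -> None:
        for (date, line), _ in self.assignments.items():
            if date.year != self.year:
                raise ValidationError(f"assignment on {date} outside year {self.year}")
            if line not in self.service_lines:
                raise ValidationError(f"unknown service line {line!r}")

    def physician_on(self, date: dt.date, service_line: str) -> str:
        try:
            return self.assignments[(date, service_line)]
        except KeyError:
            raise CoverageError(
                f"no physician assigned for {service_line} on {date}") from None

    def request_swap(self, requester: str, counterparty: str, service_line: str,
                     dates_a: Iterable[dt.date], dates_b: Iterable[dt.date]) -> SwapRequest:
        req = SwapRequest(requester, counterparty, service_line,
                          frozenset(dates_a), frozenset(dates_b),
                          request_id=f"SW{next(self._swap_ids):04d}")
        self.swap_requests.append(req)
        return req


def build_round_robin_schedule(
    year: int,
    physicians: Sequence[str],
    service_lines: Sequence[str] = DEFAULT_SERVICE_LINES,
) -> ServiceSchedule:
    """Cover every day of a year by rotating physicians through each line.

    Deterministic and staggered so no physician covers two lines on one
    day when enough physicians exist.
    """
    if not physicians:
        raise ValidationError("need at least one physician")
    assignments: dict[tuple[dt.date, str], str] = {}
    day = dt.date(year, 1, 1)
    i = 0
    while day.year == year:
        for j, line in enumerate(service_lines):
            assignments[(day, line)] = physicians[(i + j) % len(physicians)]
        day += dt.timedelta(days=1)
        i += 1
    return ServiceSchedule(year=year, assignments=assignments,
                           service_lines=tuple(service_lines))


def resolve_swap(schedule: ServiceSchedule, request: SwapRequest,
                 decision: SwapState | str) -> ServiceSchedule:
    """Accept or decline a pending swap; acceptance exchanges slots atomically.

    All slots are validated before any change: the requester must hold
    every date in their offered set and the counterparty theirs, and
    the request must describe a genuine exchange (distinct physicians,
    disjoint date sets) so no slot is written twice and silently loses
    its holder. On any violation the schedule is untouched.
    """
    decision = SwapState(decision) if isinstance(decision, str) else decision
    if request.state is not SwapState.PENDING:
        raise StateError(f"swap {request.request_id} already {request.state.value}")
    if decision is SwapState.DECLINED:
        request.state = SwapState.DECLINED
        return schedule
    if decision is not SwapState.ACCEPTED:
        raise ValidationError("decision must be accepted or declined")

    line = request.service_line
    if request.requester == request.counterparty:
        raise ConsistencyError("swap requester and counterparty must differ")
    overlap = request.dates_a & request.dates_b
    if overlap:
        raise ConsistencyError(
            f"swap date sets overlap on {sorted(overlap)}; the slot would be "
            "assigned twice")
    for date in request.dates_a:
        if schedule.physician_on(date, line) != request.requester:
            raise ConsistencyError(
                f"{request.requester} is not on {line} service on {date}")
    for date in request.dates_b:
        if schedule.physician_on(date, line) != request.counterparty:
            raise ConsistencyError(
                f"{request.counterparty} is not on {line} service on {date}")

    for date in request.dates_a:
        schedule.assignments[(date, line)] = request.counterparty
    for date in request.dates_b:
        schedule.assignments[(date, line)] = request.requester
    request.state = SwapState.ACCEPTED
    return schedule


# --- attribution -------------------------------------------------------


def attribute_report(report: Report, schedule: ServiceSchedule) -> str:
    """On-service physician for (finalization date, report's service line).

    Pure in (schedule, report dates): repeated calls agree. Raises
    :class:`CoverageError` when the schedule does not cover the date.
    """
    when = report.finalized_at or report.order.order_datetime
    if when is None:
        raise CoverageError(
            f"report {report.report_id} has no finalization or order date")
    line = report.type.code.value
    if line not in schedule.service_lines:
        raise CoverageError(f"schedule has no service line {line!r}")
    return schedule.physician_on(when.date(), line)


def schedule_to_csv(schedule: ServiceSchedule) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["date", "service_line", "physician"])
    for (date, line), phys in sorted(schedule.assignments.items(),
                                     key=lambda kv: (kv[0][0], kv[0][1])):
        writer.writerow([date.isoformat(), line, phys])
    return buf.getvalue()


def schedule_from_csv(text: str, year: int | None = None,
                      service_lines: Sequence[str] | None = None) -> ServiceSchedule:
    assignments: dict[tuple[dt.date, str], str] = {}
    lines_seen: set[str] = set()
    for row in csv.DictReader(io.StringIO(text)):
        date = dt.date.fromisoformat(row["date"])
        assignments[(date, row["service_line"])] = row["physician"]
        lines_seen.add(row["service_line"])
    if not assignments:
        raise ValidationError("schedule CSV holds no assignments")
    inferred_year = year if year is not None else next(iter(assignments))[0].year
    return ServiceSchedule(
        year=inferred_year,
        assignments=assignments,
        service_lines=tuple(service_lines) if service_lines else tuple(sorted(lines_seen)),
    )
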