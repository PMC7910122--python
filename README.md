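# epichart

A backend engine for a bespoke, specialty electronic health record for
epilepsy care. General-purpose EHRs bury epilepsy teams in clicks; the
alternative is a narrow system that speaks HL7 v2.3 to the hospital's
parent EHR and models the specialty's actual workflow. `epichart`
implements that backend as a reusable Python library plus a thin CLI:

- **HL7 v2.3 messaging** (`epichart.hl7`) — consume orders (ORM^O01)
  from multiple vendor EHRs via declarative *dialect profiles*, emit
  results (ORU^R01), charges (DFT^P03) and acknowledgements (ACK).
  Parsing and serialization are exact inverses on canonical text.
- **Collaborative report workflow** (`epichart.workflow`) — a forward-only
  state machine `AWAITING_TECHNICIAN → TECHNICIAN_COMPLETED →
  FELLOW_COMPLETED → FINALIZED → TRANSMITTED → BILLED`, with role-gated
  transitions, a replayable audit trail, an audited fellow-skip
  override, and amendment-as-correction after transmission.
- **Role-based access control** (`epichart.rbac`) — deny-by-default
  grants (role, action, resource) and per-role interface visibility;
  policy is editable YAML.
- **Ontology-driven data capture** (`epichart.ontology`) — a six-category
  epilepsy vocabulary forest (diagnoses, semiologies, epileptogenic
  zones, lateralizing signs, EEG activities, etiologies) backing
  term-picker navigation, select-don't-type entry validation, and
  descendant expansion.
- **Surgical-candidate journey tracker** (`epichart.tracker`) — 14
  work-up steps per patient, four colour-coded statuses, conjunctive
  status search, and nurse-navigator bottleneck comments.
- **Physician dashboard analytics** (`epichart.dashboard`) — outstanding
  reports, month × study-type statistics, year-long service schedules
  with atomic swap requests, and automatic report-to-physician
  attribution from the schedule.
- **Faceted cohort queries** (`epichart.cohort`) — index finalized
  reports per patient and resolve conjunctions of age/sex/term/medication
  filters (with subtree expansion) into exportable cohorts.
- **Seeded fixtures** (`epichart.fixtures`) — deterministic synthetic
  order streams, journey registries, a mini vocabulary, and a usage
  ledger mirroring the deployed system's published per-type report
  counts.

## Worked example

One order, end to end — ingest, acknowledge, document, finalize,
transmit, bill:

```python
import datetime as dt
from epichart import fixtures as fx
from epichart.hl7 import parse_message, extract_order, build_ack, serialize_message
from epichart.hl7.dialect import cerner_profile
from epichart.hl7.records import ChargeRecord
from epichart.ontology import Category
from epichart.rbac import Role, User
from epichart.workflow import ReportService, SectionPayload

raw = fx.generate_order_stream(fx.GeneratorConfig(n_patients=5, seed=7, vendor_mix=0.0))[0]
profile = cerner_profile()
msg = parse_message(raw, profile)
order = extract_order(msg, profile)
print(f"order {order.placer_id}: {order.procedure_code} for {order.mrn}")

service = ReportService(ontology=fx.mini_ontology())
tech = User("tech1", "Terry Tech", frozenset({Role.EEG_TECHNICIAN}))
fellow = User("fel1", "Finn Fellow", frozenset({Role.CLINICAL_FELLOW}))
attending = User("att1", "Avery Attending", frozenset({Role.ATTENDING_PHYSICIAN}))

report = service.create_report_from_order(order)
service.submit_section(report, tech, "technician_findings",
    SectionPayload("21-channel recording, 22 min", {Category.EEG_ACTIVITY: ["EEGA110"]}))
service.submit_section(report, fellow, "fellow_interpretation",
    SectionPayload("Left temporal sharp waves", {Category.EEG_ACTIVITY: ["EEGA120"]}))
service.finalize_report(report, attending)
oru = service.transmit_report(report, profile, actor=attending)
service.register_ack(report, "AA")   # parent EHR accepted the result
dft = service.file_billing(report, attending,
    ChargeRecord(["95816"], ["G40.209"], "att1", order.order_datetime.date(),
                 filed_at=order.order_datetime + dt.timedelta(days=1)),
    profile)
print(f"{report.report_id}: {report.state.name}, attributed to {report.attributed_physician}")
```

prints

```
order PL00700000: EEG for MRN00002
R000001: BILLED, attributed to att1
```

`R000001` ended the pipeline in `BILLED`: its result went out as an
ORU^R01 carrying one OBX per populated section (narrative plus the
selected vocabulary codes), the AA acknowledgement advanced it to
`TRANSMITTED`, and the charge left as a DFT^P03 with one FT1 per
procedure code, billed under the attributed physician.

Aggregating the bundled usage-mirror ledger reproduces the deployed
system's per-type totals:

```python
from epichart.dashboard import report_statistics
stats = report_statistics(fx.usage_ledger(), (dt.date(2019, 2, 18), dt.date(2020, 9, 21)))
for rtype, total in sorted(stats.totals_by_type.items(), key=lambda kv: -kv[1]):
    print(f"{rtype.value:12s} {total:6d}")
print(f"{'TOTAL':12s} {stats.grand_total:6d}")
```

```
EEG           15417
EMU_DAILY      2635
EMU_PHASE      1369
TOTAL         19421
```

## Command line

```bash
epichart fixtures orders --n 20 --seed 7 --out orders/
epichart ingest-order orders/order_00000.hl7 --profile cerner
epichart fixtures ontology --out terms.csv
epichart ontology children DX100 --table terms.csv
epichart rbac-check --roles eeg_technician --action finalize --resource report
epichart fixtures journeys --n 50 --seed 7 --out journeys.jsonl
epichart track search --registry journeys.jsonl \
    --where PATIENT_MANAGEMENT=COMPLETE --where SEEG=NOT_STARTED
epichart fixtures usage-ledger --out ledger.csv
epichart stats ledger.csv --from 2019-02-18 --to 2020-09-21
```

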