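# Methods

This note documents the models and procedures `epichart` implements,
the defaults it ships, what the synthetic generators do and do not
emulate, and the design choices made where the design was genuinely
open.

## Scope and shape

The engine is the backend of a bespoke epilepsy-care EHR: four
functional areas — HL7 interoperability, collaborative report
documentation, patient-journey tracking, and analytics/research query
— behind a library surface plus a thin CLI. There is no UI layer, no
network transport (messages are read from files or MLLP-framed
streams), no authentication (identity is assumed established
upstream), and no persistence engine beyond JSON-lines/CSV round-trips:
registries are in-memory and serializable.

## HL7 v2.3 engine

Messages are ordered segment lists; a segment is a 3-letter id plus
1-based fields. Field values are stored as raw wire strings
(repetitions `~`, components `^`, subcomponents `&` intact) so that
serialization is byte-exact on canonical input; accessors split on
demand. MSH follows the standard's convention that MSH-1 is the field
separator character itself and MSH-2 the four encoding characters.

Supported message types are exactly ORM^O01 (inbound orders), ORU^R01
(outbound results), DFT^P03 (outbound charges) and ACK; any other
MSH-9 is rejected with an unsupported-type error, and any MSH-12
version other than 2.3 with an unsupported-version error. Escape
sequences `\F\ \S\ \T\ \R\ \E\` are applied when logical text enters a
field and inverted on extraction; parse/serialize themselves never
rewrite content.

**Canonical form.** Trailing empty fields are trimmed on
serialization and empty vs absent fields are not distinguished. This
is the simplest convention under which `serialize(parse(t)) == t`
holds for all generator output, which is the round-trip contract the
tests enforce.

**Dialect profiles.** Upstream vendors place the same logical order
attribute (MRN, patient name, placer/filler ids, procedure code,
ordering provider, order timestamp) in different segments. A profile
is declarative config mapping each of nine logical attributes to a
`SEG-n[.c]` address plus the vendor's sending-facility codes. Two
profiles ship, named for the two upstream vendors; their specific
field placements (order identifiers on OBR for one, on ORC for the
other) are engine fixtures, not vendor documentation — real
deployments supply their own YAML. Extraction is invariant under
dialect re-rendering up to the `source_vendor` tag.

**Outbound coded entries.** The v2 standard does not prescribe where
structured vocabulary selections travel in an ORU. The engine's
convention: one OBX per populated report section in schema order;
OBX-5 carries the escaped narrative followed by one
`id^label^EPSO-LOCAL` repetition per selected term; OBX-11 is `F`
(final) or `C` (correction) for post-transmission amendments.
Receivers must be configured to match; this rendering is an engine
invention and is labelled as such.

## Report workflow

States form a total order and transitions only move forward:

```
AWAITING_TECHNICIAN → TECHNICIAN_COMPLETED → FELLOW_COMPLETED
    → FINALIZED → TRANSMITTED → BILLED
```

Ingestion is keyed on the order's placer id; a duplicate placer id is
an error rather than an upsert, because silent replacement would
corrupt the audit story. Section schemas are per-report-type config:
the default schema gives every production type a technician section
(EEG activities), a fellow interpretation, and an attending review;
the evoked-potentials type is registered in test status with no schema
yet. Whether daily unit reports really include a technician stage is
installation-specific; the default says yes and the schema is config.

Deliberate escape hatches, both audited and never silent:

- an attending may finalize directly from TECHNICIAN_COMPLETED; the
  audit entry carries the note `fellow-step-skipped`;
- after transmission, sections may be amended; the amendment produces
  a *new* correction ORU (status C) and prior transmissions are never
  mutated; state never rewinds.

Transmission success is defined as receipt of an AA acknowledgement:
`transmit_report` builds the ORU and marks the transmission pending,
and only `register_ack` with AA advances the state; AE/AR leaves the
report FINALIZED with an audit note. Billing requires state
TRANSMITTED and the billing role; the billing provider on every FT1
is the report's attributed physician.

Every audit entry is (actor, role, transition, timestamp, note);
`replay_audit` re-validates a trail against the allowed
role-transition table and non-decreasing timestamps, which is also how
the tests check role-transition soundness.

## Access control

Deny-by-default grant triples (role, action, resource type) with a
closed action/resource vocabulary: a name outside the vocabulary is a
*policy error* (misconfigured caller), distinct from an ordinary deny.
A user's effective permission is the union over their roles, so adding
a role can never remove a permission. Interface visibility is a
parallel role → interface-set map, because the system hides whole
surfaces, not just operations. The default grant table encodes the
clinical division of labour (technicians document, fellows interpret,
attendings finalize/transmit/bill, nurse navigators drive the tracker,
admin holds everything); whether fellows may transmit was open — the
default denies. The policy round-trips through YAML for editing.

## Vocabulary

The engine consumes a flattened term table, not OWL; the docstring of
`epichart.ontology` records the conversion recipe from an OWL export.
Terms form a *forest* (single parent), because multilevel-dropdown
navigation implies a tree; DAG support is future work. Load-time
validation rejects duplicate ids, dangling parents, cycles (named),
category changes along a branch, and duplicate labels within a
category. Child order is (label, term id), making two loads of the
same table identical. `descendants_of` is an iterative closure over
the child index — O(subtree) per call, adequate at vocabulary scale
(hundreds of terms).

The shipped mini vocabulary (~56 terms, six category roots, a depth-4
diagnosis chain) is synthetic and non-authoritative; a real epilepsy
and seizure ontology export exceeds 600 terms. Passing tests on the
mini vocabulary demonstrate the machinery, not clinical coverage.

## Journey tracker

Fourteen steps from unit admission through surgery to postoperative
evaluation; the list is configurable but defaults to those 14. Four
statuses (not started / ordered / scheduled / complete); the colour
attached to each is display metadata only, and "not started" is a
first-class status so storage and search share one enum. No
inter-step ordering is enforced — real work-ups branch and skip — but
a COMPLETE status cannot silently regress: reverting requires an
explicit override that leaves a comment naming the overrider. Status
updates and comments are navigator/admin actions via the policy;
comments broadcast a notification event to all teams (an event record,
not a pager integration). Search is a pure conjunction (name
substring, exact MRN, exact step statuses) returning MRN-ordered
results, and equals a brute-force predicate scan by construction —
the tests verify this on 200-journey registries. An optional hook can
mark a step ORDERED when a matching order arrives; it ships disabled
because auto-population is plausible but unconfirmed behaviour.

## Dashboard and scheduling

Statistics bucket a completed-report ledger by calendar month × study
type, with three parallel counters (completed, documented, billed)
each keyed by its own event date; "completed" (the finalization date)
drives the totals, since finalization is the closest observable to a
report being done. The grand total is re-checked against the cell sum
on every construction.

The service schedule maps (date, service line) → physician, one line
per report type by default. Swap requests exchange two physicians'
dates on one line. A request is validated fully before any mutation —
requester and counterparty must differ, the offered date sets must be
disjoint (an overlapping slot would be written twice and silently lose
its holder), and each physician must actually hold their offered
slots — so acceptance is atomic: on any violation the schedule is
byte-identical to before. Note that "one physician, one line per day"
is deliberately *not* an invariant: with four service lines and
typical staffing the rotation necessarily places a physician on more
than one line some days, so the consistency checks target slot
integrity, not daily uniqueness.

Attribution is a pure lookup: the physician on service for the
report's study type on its finalization date, raising a coverage
error off-schedule. This is what lets finalization auto-assign
authorship, and why an accepted swap immediately changes who new
reports attribute to.

## Cohort queries

Finalized reports fold into one record per patient: demographics from
the originating order, diagnosis terms (epileptic-diagnosis category)
and characteristic terms (all other categories) as unions over the
patient's reports, and free-text medication names matched
case-insensitively (no drug ontology). Age is never stored — it is
derived from date of birth against a reference date, defaulting to the
index build date so repeated queries agree. Filters are conjunctive;
term filters may expand to the full subtree, which can only grow a
cohort. Queries are patient-level (subgroups of patients, not of
reports). Exports are MRN-ordered rows with requested columns only; a
de-identification flag drops the MRN column; a full-field export
re-imports to the selected sub-index.

## Synthetic generators

All generators are pure functions of (config, seed); re-runs are
byte-identical.

- **Order streams** draw MRNs with repeats from `n_patients`, split
  vendors by `vendor_mix`, and draw study types from a mix defaulting
  to the deployed system's observed per-type shares
  (15,417 : 1369 : 2635). Orders render through the real message
  builder under each vendor's profile, so every generated message
  parses and round-trips by construction.
- **The usage ledger** reproduces, per study type, the deployed
  system's published report and distinct-patient counts (EEG
  15,417/6382 since 2019-02-18; phase 1369/1053 since 2019-07-01;
  daily 2635/312 since 2019-11-15; evoked potentials 0, still in
  test), with completion dates uniform between each type's production
  start and the 2020-09-21 census date. Only those counts are
  contractual: dates, MRN assignment and billing flags are invented,
  and per-type patient pools are disjoint, so the ledger's overall
  distinct-patient count is the per-type sum — it does not (and
  cannot) reproduce the deployment's cross-type-overlapping
  unique-patient figure, whose overlap structure is unpublished.
- **Journey registries** draw step statuses independently per step
  (40/20/15/25% across the four statuses) with dates inside the
  configured range. Real journeys are temporally ordered and
  correlated across steps; the generator makes no such claim — it
  exists to exercise search and storage, so tests passing on it show
  query correctness, not clinical realism.

## Numerical and procedural choices

- Timestamps come from an injectable clock; audit timestamps are
  clamped non-decreasing under clock skew rather than rejected.
- Sort orders are explicit everywhere results are lists (MRN order for
  registries and exports, (label, id) for vocabulary children, order
  datetime for work queues) so behaviour is deterministic.
- Degenerate inputs fail loudly at the boundary: empty term tables,
  reversed intervals, zero-patient configs and mix proportions not
  summing to 1 are validation errors, not silent defaults.
- Test and acceptance problem sizes (hundreds of messages, 200-record
  registries, 50-node random forests) were chosen as the smallest
  scales at which the brute-force oracles still exercise every branch;
  the full suite runs in a few seconds.

## Known limitations

- Forest-only vocabulary (no multi-parent terms, no reasoning, no
  SNOMED/ICD mapping).
- Vendor dialect layouts are fixtures; live integrations must supply
  actual profiles and a transport (MLLP listener) outside this
  package.
- Notifications are event records; no delivery integration.
- The report store is in-memory with file round-trips; concurrent
  multi-user persistence is out of scope.
- Statistics use the finalization date for "completed"; systems that
  distinguish recording-completion from finalization will want to feed
  `documented_date` separately.
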