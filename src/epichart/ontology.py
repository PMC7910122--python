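"""Hierarchical epilepsy vocabulary serving structured data entry.

The engine consumes a flattened term table (CSV or JSON rows of
``term_id, label, parent_id, category``) derived from an epilepsy and
seizure ontology export; description-logic reasoning is out of scope.
Terms form a forest over six clinical categories — epileptic
diagnoses, semiologies, epileptogenic zones, lateralizing signs, EEG
activities and etiologies — with one root per category. The hierarchy
backs three things: the multilevel term-picker (``children_of``),
entry validation (clinicians select terms, never free-type them), and
descendant expansion for cohort queries (``descendants_of``).

Converting an OWL export to the flat table amounts to: take each
class's IRI fragment as ``term_id``, its ``rdfs:label`` as ``label``,
its asserted (single) superclass as ``parent_id``, and the top-level
branch it sits under as ``category``; multi-parent classes must be
re-rooted to a single primary parent first, since the engine models a
forest, not a DAG.
"""

from __future__ import annotations

import csv
import enum
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from epichart.errors import (
    CycleError,
    DanglingParentError,
    DuplicateTermError,
    OntologyError,
    UnknownTermError,
)


class Category(enum.Enum):
    EPILEPTIC_DIAGNOSIS = "epileptic_diagnosis"
    SEMIOLOGY = "semiology"
    EPILEPTOGENIC_ZONE = "epileptogenic_zone"
    LATERALIZING_SIGN = "lateralizing_sign"
    EEG_ACTIVITY = "eeg_activity"
    ETIOLOGY = "etiology"


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    label: str
    parent_id: str | None  # None ⇒ category root
    category: Category

    @property
    def is_root(self) -> bool:
        return self.parent_id is None


@dataclass
class Ontology:
    """Validated term forest with a deterministic child index."""

    terms: dict[str, OntologyTerm]
    child_index: dict[str | None, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    @property
    def roots(self) -> list[OntologyTerm]:
        return [self.terms[t] for t in self.child_index.get(None, [])]


def load_ontology(rows: Iterable[tuple[str, str, str | None, str]]) -> Ontology:
    """Build and validate an :class:`Ontology` from flat rows.

    Each row is ``(term_id, label, parent_id, category)``; an empty or
    None parent_id marks a category root. Children are ordered by
    (label, term_id) so two loads of the same table are identical.

    Raises
    ------
    DuplicateTermError, DanglingParentError, CycleError, OntologyError
        On duplicate ids, parents that don't exist, parent-link cycles,
        unknown category names, category mismatch along a branch, or
        duplicate labels within a category.
    """
    terms: dict[str, OntologyTerm] = {}
    for term_id, label, parent_id, category in rows:
        if term_id in terms:
            raise DuplicateTermError(f"duplicate term id {term_id!r}")
        try:
            cat = Category(category)
        except ValueError:
            raise OntologyError(
                f"term {term_id!r} has unknown category {category!r}; "
                f"valid: {[c.value for c in Category]}"
            ) from None
        terms[term_id] = OntologyTerm(term_id, label, parent_id or None, cat)
    if not terms:
        raise OntologyError("term table is empty")

    for t in terms.values():
        if t.parent_id is not None and t.parent_id not in terms:
            raise DanglingParentError(
                f"term {t.term_id!r} references missing parent {t.parent_id!r}"
            )

    # cycle check by walking each term's ancestor chain
    state: dict[str, int] = {}  # 0 in-progress, 1 done
    for start in terms:
        chain = []
        node: str | None = start
        while node is not None and state.get(node) != 1:
            if state.get(node) == 0:
                i = chain.index(node)
                raise CycleError(chain[i:] + [node])
            state[node] = 0
            chain.append(node)
            node = terms[node].parent_id
        for n in chain:
            state[n] = 1

    # category consistency and per-category label uniqueness
    for t in terms.values():
        if t.parent_id is not None and terms[t.parent_id].category != t.category:
            raise OntologyError(
                f"term {t.term_id!r} ({t.category.value}) has parent "
                f"{t.parent_id!r} of category {terms[t.parent_id].category.value}"
            )
    seen_labels: set[tuple[Category, str]] = set()
    for t in terms.values():
        key = (t.category, t.label)
        if key in seen_labels:
            raise OntologyError(
                f"label {t.label!r} duplicated within category {t.category.value}"
            )
        seen_labels.add(key)

    child_index: dict[str | None, list[str]] = {}
    for t in sorted(terms.values(), key=lambda x: (x.label, x.term_id)):
        child_index.setdefault(t.parent_id, []).append(t.term_id)
    return Ontology(terms=terms, child_index=child_index)


def load_ontology_csv(path: str | Path) -> Ontology:
    """Load from a CSV with header ``term_id,label,parent_id,category``."""
    with open(path, newline="") as fh:
        return _from_dict_rows(csv.DictReader(fh), path)


def load_ontology_json(path: str | Path) -> Ontology:
    """Load from a JSON array of row objects."""
    return _from_dict_rows(json.loads(Path(path).read_text()), path)


def _from_dict_rows(rows: Iterable[dict], source) -> Ontology:
    try:
        return load_ontology(
            (r["term_id"], r["label"], r.get("parent_id") or None, r["category"])
            for r in rows
        )
    except KeyError as exc:
        raise OntologyError(f"term table {source} missing column {exc}") from None


def dump_ontology_csv(ont: Ontology) -> str:
    """Render the term table back to CSV text (stable row order)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["term_id", "label", "parent_id", "category"])
    for term_id in sorted(ont.terms):
        t = ont.terms[term_id]
        writer.writerow([t.term_id, t.label, t.parent_id or "", t.category.value])
    return buf.getvalue()


def children_of(ont: Ontology, term_id: str) -> list[OntologyTerm]:
    """Direct children in deterministic (label, term_id) order."""
    ont.term(term_id)
    return [ont.terms[c] for c in ont.child_index.get(term_id, [])]


def descendants_of(ont: Ontology, term_id: str) -> set[str]:
    """All term ids strictly below ``term_id`` (transitive closure)."""
    ont.term(term_id)
    out: set[str] = set()
    stack = list(ont.child_index.get(term_id, []))
    while stack:
        node = stack.pop()
        out.add(node)
        stack.extend(ont.child_index.get(node, []))
    return out


@dataclass(frozen=True)
class Violation:
    term_id: str
    reason: str  # "unknown-term" | "wrong-category"
    detail: str = ""


def validate_entry(
    ont: Ontology, field_category: Category | str, term_ids: Sequence[str]
) -> list[Violation]:
    """Check term selections against the category a form field accepts.

    Returns an empty list when every id exists and belongs to
    ``field_category``; otherwise one :class:`Violation` per offending
    id. Free-typed strings that are not term ids surface as
    ``unknown-term`` violations — the contract that clinicians select
    vocabulary items rather than typing them.
    """
    cat = Category(field_category) if isinstance(field_category, str) else field_category
    violations: list[Violation] = []
    for tid in term_ids:
        if tid not in ont:
            violations.append(Violation(tid, "unknown-term",
                                        f"{tid!r} is not in the vocabulary"))
        elif ont.terms[tid].category != cat:
            violations.append(Violation(
                tid, "wrong-category",
                f"{tid!r} is {ont.terms[tid].category.value}, field expects {cat.value}"))
    return violations
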