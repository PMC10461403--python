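"""Corpus serialization, annotation merging, and multilevel summaries.

Corpora are stored either as JSONL (one object per note) or CSV with
RFC-4180 quoting. Annotation files are CSV with one row per
(note_id, annotator_id), six binary label columns and a JSON-encoded
rationale list.

The multilevel summary reproduces the descriptive table of the study
corpus: for each risk factor, the count and percentage of *notes*,
*patients* and *sites* with at least one positive note, at the printed
precision of that table (one decimal for notes/patients, integer
percentages for sites).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datatypes import LABELS, AdjudicatedRecord, Annotation, ClinicalNote, RiskFactorVector
from .errors import IntegrityError, SchemaError, UnresolvedDisagreementError

_REQUIRED_COLUMNS = ("note_id", "patient_id", "site_id", "text")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise SchemaError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise SchemaError(f"cannot infer format from {path!r}; pass format=")


def read_corpus(path: str | Path, format: str | None = None) -> list[ClinicalNote]:
    """Read a corpus file into a list of notes, preserving row order.

    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` for duplicate note ids or empty text.
    """
    fmt = _infer_format(path, format)
    rows: list[dict] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if line.strip():
                    rows.append(json.loads(line))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty CSV with no header")
            rows = list(reader)

    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    for i, row in enumerate(rows):
        missing = [c for c in _REQUIRED_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise SchemaError(f"{path} row {i}: missing required column(s) {missing}")
        note_id = str(row["note_id"])
        if note_id in seen:
            raise IntegrityError(f"{path}: duplicate note_id {note_id!r}")
        seen.add(note_id)
        note_type = row.get("note_type")
        if note_type in ("", None):
            note_type = None
        notes.append(
            ClinicalNote(
                note_id=note_id,
                patient_id=str(row["patient_id"]),
                site_id=str(row["site_id"]),
                text=str(row["text"]),
                note_type=note_type,
            )
        )
    return notes


def write_corpus(notes: list[ClinicalNote], path: str | Path, format: str | None = None) -> None:
    """Write notes to JSONL or CSV; lossless round-trip with :func:`read_corpus`."""
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for n in notes:
                obj = {
                    "note_id": n.note_id,
                    "patient_id": n.patient_id,
                    "site_id": n.site_id,
                    "text": n.text,
                }
                if n.note_type is not None:
                    obj["note_type"] = n.note_type
                fh.write(json.dumps(obj) + "\n")
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(_REQUIRED_COLUMNS) + ["note_type"])
            for n in notes:
                writer.writerow(
                    [n.note_id, n.patient_id, n.site_id, n.text, n.note_type or ""]
                )


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read an annotation CSV: one row per (note_id, annotator_id)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty CSV with no header")
        required = ("note_id", "annotator_id") + LABELS
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        out = []
        for row in reader:
            rationales = json.loads(row.get("rationales") or "[]")
            out.append(
                Annotation(
                    note_id=row["note_id"],
                    annotator_id=row["annotator_id"],
                    labels=RiskFactorVector.from_dict(row),
                    rationales=[(lab, snip) for lab, snip in rationales],
                )
            )
        return out


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "annotator_id", *LABELS, "rationales"])
        for a in annotations:
            writer.writerow(
                [a.note_id, a.annotator_id]
                + [getattr(a.labels, lab) for lab in LABELS]
                + [json.dumps([list(r) for r in a.rationales])]
            )


def merge_annotations(
    a: Annotation,
    b: Annotation,
    arbiter: Annotation | None = None,
    *,
    note: ClinicalNote,
) -> AdjudicatedRecord:
    """Merge dual annotations of one note into a gold record.

    If the two annotators agree on all six labels the record is ``agreed``;
    otherwise the arbiter's labels decide and the record is ``arbitrated``.
    Rationales from all sources are kept only if consistent with the final
    labels (the losing annotator's evidence for a rejected label is dropped).
    """
    if a.note_id != b.note_id:
        raise IntegrityError(f"annotation note ids differ: {a.note_id!r} vs {b.note_id!r}")
    if a.note_id != note.note_id:
        raise IntegrityError(f"annotations are for {a.note_id!r}, note is {note.note_id!r}")
    sources = [a, b]
    if a.labels == b.labels:
        final = a.labels
        provenance = "agreed"
    else:
        conflicting = [
            lab for lab in LABELS if getattr(a.labels, lab) != getattr(b.labels, lab)
        ]
        if arbiter is None:
            raise UnresolvedDisagreementError(a.note_id, conflicting)
        if arbiter.note_id != a.note_id:
            raise IntegrityError(
                f"arbiter annotation is for {arbiter.note_id!r}, expected {a.note_id!r}"
            )
        final = arbiter.labels
        provenance = "arbitrated"
        sources.append(arbiter)

    rationales: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for src in sources:
        for lab, snip in src.rationales:
            if getattr(final, lab) == 1 and (lab, snip) not in seen:
                seen.add((lab, snip))
                rationales.append((lab, snip))
    return AdjudicatedRecord(note=note, labels=final, rationales=rationales, provenance=provenance)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 always rounds away from zero)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


#: units of analysis and the decimal precision of their printed percentages
_UNITS = (("notes", 1), ("patients", 1), ("sites", 0))


@dataclass
class MultilevelSummary:
    """Per-label counts/percentages at note, patient and site level."""

    totals: dict[str, int]  # unit -> number of units
    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # unit -> label -> n
    percents: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for unit, _prec in _UNITS:
            for lab in LABELS:
                rows.append(
                    {
                        "unit": unit,
                        "unit_total": self.totals[unit],
                        "label": lab,
                        "count": self.counts[unit][lab],
                        "percent": self.percents[unit][lab],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def multilevel_summary(records: list[AdjudicatedRecord]) -> MultilevelSummary:
    """Count, per risk factor, notes / distinct patients / distinct sites
    with at least one positive note.

    A label is attributed to a patient (site) if *any* of its notes carries
    the label, so label-wise ``site count <= patient count <= note count``.
    """
    if not records:
        raise IntegrityError("multilevel_summary of an empty record list")
    patients = {r.note.patient_id for r in records}
    sites = {r.note.site_id for r in records}
    totals = {"notes": len(records), "patients": len(patients), "sites": len(sites)}

    counts = {unit: {lab: 0 for lab in LABELS} for unit, _ in _UNITS}
    for lab in LABELS:
        pos = [r for r in records if getattr(r.labels, lab) == 1]
        counts["notes"][lab] = len(pos)
        counts["patients"][lab] = len({r.note.patient_id for r in pos})
        counts["sites"][lab] = len({r.note.site_id for r in pos})

    percents = {
        unit: {
            lab: round_half_up(100.0 * counts[unit][lab] / totals[unit], prec)
            for lab in LABELS
        }
        for unit, prec in _UNITS
    }
    return MultilevelSummary(totals=totals, counts=counts, percents=percents)
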