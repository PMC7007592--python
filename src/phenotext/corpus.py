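"""Clinical-note corpus model: JSON loading, validation, grouping, splitting.

A corpus is a flat JSON array of note records::

    [
      {
        "note_id": "n001",
        "patient_id": "p01",
        "text": "Patient denies pelvic pain. ...",
        "note_date": "2016-03-02",          # optional, ISO-8601
        "note_type": "progress note",       # optional
        "metadata": {"class": "symptomatic"}
      },
      ...
    ]

The gold-standard class label, when known, lives inside ``metadata`` under a
user-named key (``label_key``).  Labels attach to the *patient*: all labeled
notes of one patient must agree, and any disagreement is a hard error rather
than a majority vote — silent voting would corrupt the gold standard.
Unlabeled patients are first-class citizens (the trained model is meant to be
applied to new, unannotated data).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ClinicalNote",
    "PatientRecord",
    "Corpus",
    "SplitSpec",
    "CorpusValidationError",
    "load_corpus",
    "corpus_from_notes",
    "write_corpus",
    "split_corpus",
    "export_labels_csv",
]

_NOTE_KEYS = {"note_id", "patient_id", "text", "note_date", "note_type", "metadata"}


class CorpusValidationError(ValueError):
    """A corpus file or in-memory corpus violates the documented schema."""


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text note tied to a patient.

    ``metadata`` is a string-to-string map; one designated key may hold the
    gold-standard class label.  Empty text is legal (a real observation of
    absence) and is preserved as ``""``, never null.
    """

    note_id: str
    patient_id: str
    text: str = ""
    note_date: str | None = None
    note_type: str | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.note_id:
            raise CorpusValidationError("note_id must be nonempty")
        if not self.patient_id:
            raise CorpusValidationError(f"note {self.note_id!r}: patient_id must be nonempty")
        if not isinstance(self.text, str):
            raise CorpusValidationError(f"note {self.note_id!r}: text must be a string")

    def label(self, label_key: str) -> str | None:
        return self.metadata.get(label_key)


@dataclass(frozen=True)
class PatientRecord:
    """All notes of one patient plus the resolved gold label (if any).

    Notes are ordered by (note_date, note_id) for reproducible iteration;
    the downstream mean aggregation is order-invariant regardless.
    """

    patient_id: str
    notes: tuple[ClinicalNote, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.notes:
            raise CorpusValidationError(f"patient {self.patient_id!r}: at least one note required")
        for n in self.notes:
            if n.patient_id != self.patient_id:
                raise CorpusValidationError(
                    f"patient {self.patient_id!r}: note {n.note_id!r} belongs to {n.patient_id!r}"
                )

    @property
    def n_notes(self) -> int:
        return len(self.notes)


@dataclass(frozen=True)
class Corpus:
    """An immutable collection of patients keyed by patient_id."""

    patients: Mapping[str, PatientRecord]
    label_key: str

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.patients)

    @property
    def class_names(self) -> list[str]:
        """Distinct labels present on labeled patients, sorted."""
        return sorted({p.label for p in self.patients.values() if p.label is not None})

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def labels(self) -> dict[str, str | None]:
        return {pid: self.patients[pid].label for pid in self.patient_ids}

    def subset(self, patient_ids: Iterable[str]) -> "Corpus":
        ids = list(patient_ids)
        missing = [p for p in ids if p not in self.patients]
        if missing:
            raise KeyError(f"unknown patient_ids: {missing}")
        return Corpus({p: self.patients[p] for p in ids}, self.label_key)

    def iter_notes(self) -> Iterable[ClinicalNote]:
        for pid in self.patient_ids:
            yield from self.patients[pid].notes


@dataclass(frozen=True)
class SplitSpec:
    """Allocation of patients to a training vs held-out side.

    ``fraction`` is the training share in (0, 1); alternatively ``counts``
    gives explicit per-class training counts.  With ``stratified`` the
    allocation is applied per class (closed form: round(fraction * n_class),
    clamped so both sides stay nonempty).
    """

    fraction: float | None = 0.5
    counts: Mapping[str, int] | None = None
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if (self.fraction is None) == (self.counts is None):
            raise ValueError("exactly one of fraction or counts must be given")
        if self.fraction is not None and not (0.0 < self.fraction < 1.0):
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")
        if self.counts is not None and any(c <= 0 for c in self.counts.values()):
            raise ValueError("per-class counts must be positive")


def _validate_note_record(rec: object, idx: int) -> ClinicalNote:
    if not isinstance(rec, dict):
        raise CorpusValidationError(f"record {idx}: expected an object, got {type(rec).__name__}")
    unknown = set(rec) - _NOTE_KEYS
    if unknown:
        raise CorpusValidationError(f"record {idx}: unknown keys {sorted(unknown)}")
    for req in ("note_id", "patient_id"):
        if req not in rec:
            raise CorpusValidationError(f"record {idx}: missing required key {req!r}")
    meta = rec.get("metadata", {})
    if not isinstance(meta, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in meta.items()
    ):
        raise CorpusValidationError(f"record {idx}: metadata must map strings to strings")
    try:
        return ClinicalNote(
            note_id=rec["note_id"],
            patient_id=rec["patient_id"],
            text=rec.get("text", ""),
            note_date=rec.get("note_date"),
            note_type=rec.get("note_type"),
            metadata=dict(meta),
        )
    except CorpusValidationError as e:
        raise CorpusValidationError(f"record {idx}: {e}") from None


def corpus_from_notes(notes: Sequence[ClinicalNote], label_key: str) -> Corpus:
    """Group notes by patient, resolve per-patient labels, validate invariants."""
    seen_ids: set[str] = set()
    by_patient: dict[str, list[ClinicalNote]] = {}
    for n in notes:
        if n.note_id in seen_ids:
            raise CorpusValidationError(f"duplicate note_id {n.note_id!r}")
        seen_ids.add(n.note_id)
        by_patient.setdefault(n.patient_id, []).append(n)

    patients: dict[str, PatientRecord] = {}
    for pid, plist in by_patient.items():
        labels = {lbl for n in plist if (lbl := n.label(label_key)) is not None}
        if len(labels) > 1:
            raise CorpusValidationError(
                f"patient {pid!r}: conflicting labels {sorted(labels)} under key {label_key!r}"
            )
        ordered = tuple(sorted(plist, key=lambda n: (n.note_date or "", n.note_id)))
        patients[pid] = PatientRecord(pid, ordered, labels.pop() if labels else None)
    return Corpus(patients, label_key)


def load_corpus(path: str | Path, label_key: str) -> Corpus:
    """Load and validate a corpus from the JSON dialect described above."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as e:
        raise CorpusValidationError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from None
    if not isinstance(data, list):
        raise CorpusValidationError(f"{path}: top level must be an array of note records")
    notes = [_validate_note_record(rec, i) for i, rec in enumerate(data)]
    return corpus_from_notes(notes, label_key)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize so that load_corpus round-trips field-for-field."""
    records = []
    for note in corpus.iter_notes():
        rec: dict[str, object] = {
            "note_id": note.note_id,
            "patient_id": note.patient_id,
            "text": note.text,
            "metadata": dict(note.metadata),
        }
        if note.note_date is not None:
            rec["note_date"] = note.note_date
        if note.note_type is not None:
            rec["note_type"] = note.note_type
        records.append(rec)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")


def _train_count(n: int, fraction: float) -> int:
    # round-half-up, clamped so both sides are nonempty
    k = int(math.floor(fraction * n + 0.5))
    return min(max(k, 1), n - 1)


def split_corpus(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus]:
    """Patient-disjoint train/test partition, deterministic given the seed.

    All patients must be labeled.  Stratified splitting allocates
    ``round(fraction * n_class)`` (or the explicit per-class count) of each
    class to the training side; each class therefore needs >= 2 patients.
    """
    labels = corpus.labels()
    unlabeled = [pid for pid, lbl in labels.items() if lbl is None]
    if unlabeled:
        raise CorpusValidationError(f"cannot split with unlabeled patients: {sorted(unlabeled)}")

    rng = np.random.default_rng(spec.seed)
    train_ids: list[str] = []
    test_ids: list[str] = []

    if spec.stratified:
        for cls in corpus.class_names:
            members = sorted(pid for pid, lbl in labels.items() if lbl == cls)
            if len(members) < 2:
                raise CorpusValidationError(
                    f"class {cls!r} has {len(members)} patient(s); stratified split needs >= 2"
                )
            if spec.counts is not None:
                if cls not in spec.counts:
                    raise ValueError(f"counts missing class {cls!r}")
                k = spec.counts[cls]
                if k >= len(members):
                    raise ValueError(f"class {cls!r}: count {k} leaves empty test side")
            else:
                k = _train_count(len(members), spec.fraction)  # type: ignore[arg-type]
            perm = rng.permutation(len(members))
            train_ids += [members[i] for i in perm[:k]]
            test_ids += [members[i] for i in perm[k:]]
    else:
        members = corpus.patient_ids
        if spec.counts is not None:
            raise ValueError("per-class counts require stratified=True")
        k = _train_count(len(members), spec.fraction)  # type: ignore[arg-type]
        perm = rng.permutation(len(members))
        train_ids = [members[i] for i in perm[:k]]
        test_ids = [members[i] for i in perm[k:]]

    return corpus.subset(sorted(train_ids)), corpus.subset(sorted(test_ids))


def export_labels_csv(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label"])
        for pid in corpus.patient_ids:
            w.writerow([pid, corpus.patients[pid].label or ""])
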