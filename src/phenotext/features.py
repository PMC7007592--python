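"""Regex feature compilation and the sentence -> note -> patient engine.

The processing engine turns each patient's free text into one numeric vector:

1. each note is segmented into sentences;
2. for every sentence, the number of non-overlapping matches of each named
   regular expression is counted (one coordinate per feature);
3. per-sentence count vectors are summed over the note's sentences;
4. per-note vectors are averaged over the patient's notes.

The result — the patient vector — is what the classifiers consume.  Features
are authored by clinical experts as plain regular expressions; both presence
patterns ("pelvic pain") and negation patterns ("(denies|no).{0,35}pelvic
pain") are ordinary features occupying their own coordinates, which is how
absence-statements get distinguished from presence-statements.

Matching is case-sensitive by default because clinical feature authors encode
case deliberately ("(D|d)iabetes", "(s|S)itus"); a per-feature override is
available.  Counting is non-overlapping left-to-right, and a pattern can
never match across a sentence boundary because segmentation happens first.
Text without sentence punctuation stays one sentence, so long-range patterns
(spans of hundreds of characters) remain usable.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import ClinicalNote, Corpus, PatientRecord

__all__ = [
    "FeatureDefinition",
    "FeatureSet",
    "PatientVector",
    "FeatureCompileError",
    "load_features",
    "write_features",
    "segment_sentences",
    "count_matches",
    "match_spans",
    "vectorize_note",
    "vectorize_patient",
    "vectorize_corpus",
    "vectors_to_matrix",
    "export_feature_matrix",
    "export_audit_spans",
]


class FeatureCompileError(ValueError):
    """A feature's regular expression does not compile.

    Raised eagerly at definition time and names both the feature and the
    compiler's diagnostic, so typos in expert-authored pattern files (a bad
    escape, an unclosed bracket) surface immediately instead of being
    silently accepted.
    """


@dataclass(frozen=True)
class FeatureDefinition:
    """A named regular-expression feature."""

    name: str
    pattern: str
    case_sensitive: bool = True
    _compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")
        flags = 0 if self.case_sensitive else re.IGNORECASE
        try:
            compiled = re.compile(self.pattern, flags)
        except re.error as e:
            raise FeatureCompileError(
                f"feature {self.name!r}: pattern {self.pattern!r} does not compile: {e}"
            ) from None
        object.__setattr__(self, "_compiled", compiled)

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled


@dataclass(frozen=True)
class FeatureSet:
    """Ordered, nonempty list of features; order fixes vector coordinates."""

    features: tuple[FeatureDefinition, ...]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a FeatureSet must contain at least one feature")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass(frozen=True)
class PatientVector:
    """Mean of a patient's per-note count vectors; the unit of classification."""

    patient_id: str
    values: tuple[float, ...]
    n_notes: int
    label: str | None = None


def load_features(path: str | Path) -> FeatureSet:
    """Read a feature file: JSON array of {name, pattern, case_sensitive}
    or a two-column CSV (name,pattern) for clinician-authored lists."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        defs = []
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        if rows and [c.strip().lower() for c in rows[0][:2]] == ["name", "pattern"]:
            rows = rows[1:]
        for i, row in enumerate(rows):
            if len(row) < 2:
                raise ValueError(f"{path}: row {i}: expected columns name,pattern")
            defs.append(FeatureDefinition(row[0], row[1]))
        return FeatureSet(tuple(defs))

    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"{path}: feature file must be a JSON array")
    defs = [
        FeatureDefinition(
            name=rec["name"],
            pattern=rec["pattern"],
            case_sensitive=rec.get("case_sensitive", True),
        )
        for rec in data
    ]
    return FeatureSet(tuple(defs))


def write_features(fs: FeatureSet, path: str | Path) -> None:
    records = [
        {"name": f.name, "pattern": f.pattern, "case_sensitive": f.case_sensitive} for f in fs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


# --- sentence segmentation -------------------------------------------------
#
# Rule-based: hard boundaries at newlines; within a line, a run of [.?!]
# followed by whitespace (or end of line) terminates a sentence, except when
# a lone period follows a known abbreviation.  Deterministic and auditable;
# text with no sentence punctuation stays a single sentence.

_ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "pt", "vs", "st", "jr", "sr", "prof", "approx", "dept"}
)
_TERMINATOR = re.compile(r"[.?!]+(?=\s|$)")
_LAST_WORD = re.compile(r"([A-Za-z]+)$")


def segment_sentences(text: str) -> list[str]:
    """Split free text into sentences (empty input -> empty list)."""
    sentences: list[str] = []
    for line in text.split("\n"):
        start = 0
        for m in _TERMINATOR.finditer(line):
            if m.group() == ".":
                w = _LAST_WORD.search(line, start, m.start())
                if w and w.group(1).lower() in _ABBREVIATIONS:
                    continue
            chunk = line[start : m.end()].strip()
            if chunk:
                sentences.append(chunk)
            start = m.end()
        tail = line[start:].strip()
        if tail:
            sentences.append(tail)
    return sentences


# --- matching and aggregation ----------------------------------------------


def count_matches(feature: FeatureDefinition, sentence: str) -> int:
    """Non-overlapping, leftmost-first match count (>= 0)."""
    return sum(1 for _ in feature.compiled.finditer(sentence))


def match_spans(feature: FeatureDefinition, text: str) -> list[tuple[int, int]]:
    """Half-open 0-based character offsets of the matches count_matches counts."""
    return [m.span() for m in feature.compiled.finditer(text)]


def sentence_counts(fs: FeatureSet, sentence: str) -> np.ndarray:
    return np.array([count_matches(f, sentence) for f in fs], dtype=np.int64)


def vectorize_note(note: ClinicalNote, fs: FeatureSet) -> np.ndarray:
    """Column-sum of per-sentence counts over the note (zero vector if empty)."""
    total = np.zeros(len(fs), dtype=np.int64)
    for sent in segment_sentences(note.text):
        total += sentence_counts(fs, sent)
    return total


def vectorize_patient(record: PatientRecord, fs: FeatureSet) -> PatientVector:
    """Arithmetic mean of the patient's note vectors.

    Empty notes contribute zero vectors and still count toward the mean's
    denominator — an empty note is a real observation of absence.
    """
    if record.n_notes == 0:  # unreachable through PatientRecord, kept as guard
        raise ValueError(f"patient {record.patient_id!r} has no notes; cannot form a mean")
    stacked = np.stack([vectorize_note(n, fs) for n in record.notes])
    mean = stacked.mean(axis=0)
    return PatientVector(
        patient_id=record.patient_id,
        values=tuple(float(v) for v in mean),
        n_notes=record.n_notes,
        label=record.label,
    )


def vectorize_corpus(corpus: Corpus, fs: FeatureSet) -> list[PatientVector]:
    """One PatientVector per patient, sorted by patient_id; labels carried along."""
    return [vectorize_patient(corpus.patients[pid], fs) for pid in corpus.patient_ids]


def vectors_to_matrix(vectors: Sequence[PatientVector]) -> tuple[np.ndarray, list[str]]:
    """Stack vectors into an (n_patients, n_features) float matrix."""
    X = np.array([v.values for v in vectors], dtype=float)
    return X, [v.patient_id for v in vectors]


def export_feature_matrix(
    vectors: Sequence[PatientVector], fs: FeatureSet, path: str | Path
) -> None:
    """CSV "patient_id,label,<feature names...>" for external analysis."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label", *fs.names])
        for v in vectors:
            w.writerow([v.patient_id, v.label or "", *[repr(x) for x in v.values]])


def export_audit_spans(
    notes: Iterable[ClinicalNote], fs: FeatureSet, path: str | Path
) -> None:
    """Per-note match offsets as JSON — a headless audit trail of what matched
    where, the batch analogue of highlighting matches in a note browser."""
    records = []
    for note in notes:
        offset = 0
        for sent in segment_sentences(note.text):
            pos = note.text.index(sent, offset)
            for f in fs:
                for start, end in match_spans(f, sent):
                    records.append(
                        {
                            "note_id": note.note_id,
                            "feature": f.name,
                            "start": pos + start,
                            "end": pos + end,
                        }
                    )
            offset = pos + len(sent)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")
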