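import re

import numpy as np
import pytest

from phenotext import (
    ClinicalNote,
    FeatureDefinition,
    FeatureSet,
    corpus_from_notes,
    segment_sentences,
)

# word pool for random note text; includes fragments that do and do not
# complete feature phrases, plus sentence punctuation hazards
WORDS = (
    "patient pelvic pain denies no fibroid bleeding heavy exam stable BMI "
    "diabetes Diabetes insulin tubes ear Ear normal plan followup vs dr"
).split()

PATTERN_POOL = [
    ("pelvic_pain", r"pelvic pain", True),
    ("denies_pp", r"(denies|no).{0,35}pelvic pain", True),
    ("diabetes", r"(D|d)iabetes", True),
    ("bmi", r"\bBMI\b", True),
    ("ear_tubes", r"(E|e)ar tubes?", True),
    ("bleeding", r"(vaginal |heavy )?bleeding", True),
    ("insulin", r"insulin", False),  # case-insensitive variant
    ("fibroid", r"fibroid(s)?", True),
]


def brute_force_count(pattern: str, case_sensitive: bool, sentence: str) -> int:
    """Independent non-overlapping leftmost scan, written without finditer."""
    comp = re.compile(pattern, 0 if case_sensitive else re.IGNORECASE)
    count, pos = 0, 0
    while pos <= len(sentence):
        m = comp.search(sentence, pos)
        if m is None:
            break
        count += 1
        pos = m.end() if m.end() > m.start() else m.start() + 1
    return count


def brute_force_patient_vectors(corpus, fs):
    """Naive triple loop patients x sentences x features -> patient means."""
    out = {}
    for pid in corpus.patient_ids:
        rec = corpus.patients[pid]
        note_vecs = []
        for note in rec.notes:
            totals = [0] * len(fs)
            for sent in segment_sentences(note.text):
                for j, f in enumerate(fs):
                    totals[j] += brute_force_count(f.pattern, f.case_sensitive, sent)
            note_vecs.append(totals)
        out[pid] = np.array(note_vecs, dtype=float).mean(axis=0)
    return out


def random_corpus(rng: np.random.Generator, max_patients=20, max_notes=5):
    """A random little corpus of punctuated word-salad notes."""
    n_pat = int(rng.integers(2, max_patients + 1))
    notes = []
    for i in range(n_pat):
        pid = f"p{i:03d}"
        for j in range(int(rng.integers(1, max_notes + 1))):
            k = int(rng.integers(0, 40))
            toks = []
            for _ in range(k):
                toks.append(WORDS[int(rng.integers(len(WORDS)))])
                r = rng.random()
                if r < 0.12:
                    toks[-1] += "."
                elif r < 0.16:
                    toks[-1] += "?"
                elif r < 0.20:
                    toks[-1] += "\n"
            text = " ".join(toks)
            notes.append(
                ClinicalNote(f"{pid}-n{j}", pid, text, metadata={"class": f"c{i % 2}"})
            )
    return corpus_from_notes(notes, "class")


@pytest.fixture
def feature_pool():
    return FeatureSet(
        tuple(FeatureDefinition(n, p, cs) for n, p, cs in PATTERN_POOL)
    )


@pytest.fixture
def tiny_corpus():
    notes = [
        ClinicalNote("n1", "pA", "Patient denies pelvic pain. BMI is 42.", metadata={"class": "noncase"}),
        ClinicalNote("n2", "pA", "Stable. Plan followup.", metadata={"class": "noncase"}),
        ClinicalNote("n3", "pB", "Severe pelvic pain with heavy bleeding.", metadata={"class": "case"}),
    ]
    return corpus_from_notes(notes, "class")


def separable_vectors(n_per_class=10, gap=5.0, seed=0):
    """Two linearly separable point clouds as labeled PatientVectors."""
    from phenotext import PatientVector

    rng = np.random.default_rng(seed)
    vecs = []
    for i in range(n_per_class):
        vecs.append(
            PatientVector(f"a{i:02d}", tuple(rng.normal(0, 0.3, 2)), 1, label="case")
        )
        vecs.append(
            PatientVector(f"b{i:02d}", tuple(rng.normal(gap, 0.3, 2)), 1, label="noncase")
        )
    return vecs
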