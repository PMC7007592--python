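"""Synthetic clinical-note corpora with planted, regex-matchable phrases.

The generator emulates the statistical structure a note classifier consumes:
multiple notes per patient, class-dependent planted phrases ("pelvic pain"),
negated surface forms ("denies pelvic pain"), near-miss decoys, and neutral
filler text.  It makes no attempt at clinically realistic narrative — the
point is a corpus whose exact per-feature match counts are known at
generation time, so every pipeline stage can be tested end to end without
access to real EHR notes.

Self-consistency guarantees, enforced (not assumed) at generation time:

* every positive phrase matches its feature's pattern;
* every decoy matches no feature at all;
* every filler sentence is verified match-free before it is emitted;
* each planted phrase occupies its own sentence, so phrases cannot interact,
  and the recorded GroundTruth counts are exactly what the feature engine
  will recount on the generated text.

Violations raise :class:`GenerationError` rather than silently producing a
corpus whose ground truth is wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import ClinicalNote, Corpus, corpus_from_notes
from .features import FeatureDefinition, FeatureSet, count_matches, segment_sentences

__all__ = [
    "PhraseBank",
    "ClassSpec",
    "GeneratorConfig",
    "GroundTruth",
    "GenerationError",
    "Scenario",
    "generate_corpus",
    "make_benchmark_suite",
    "DEFAULT_FILLER_VOCABULARY",
]

LABEL_KEY = "class"

# Neutral clinical boilerplate; verified at generation time to produce zero
# feature matches in any emitted order.
DEFAULT_FILLER_VOCABULARY = (
    "patient", "seen", "in", "clinic", "today", "for", "routine", "followup",
    "vitals", "stable", "and", "reviewed", "plan", "to", "continue", "current",
    "medications", "as", "prescribed", "return", "visit", "scheduled", "labs",
    "ordered", "discussed", "with", "family", "rest", "encouraged", "diet",
    "exercise", "counseling", "provided", "general", "appearance", "well",
)


class GenerationError(ValueError):
    """A phrase bank or filler vocabulary failed match/non-match verification."""


_FORBIDDEN_CHARS = set(".?!\n")


@dataclass(frozen=True)
class PhraseBank:
    """Surface strings for one feature.

    ``positives`` must match the feature's pattern; ``negated`` are the
    negated surface forms of the same clinical concept (e.g. "denies pelvic
    pain"), optionally verified against a designated negation feature;
    ``decoys`` are near misses that must match nothing.
    """

    positives: tuple[str, ...]
    negated: tuple[str, ...] = ()
    decoys: tuple[str, ...] = ()
    negated_feature: str | None = None


@dataclass(frozen=True)
class ClassSpec:
    """One class of patients and its per-feature emission probabilities.

    ``emission`` maps feature name -> probability that a sentence slot of
    this class plants a phrase for that feature.  ``negation_rate`` (class
    override of the config-wide rate) is the probability a planted phrase
    uses its negated surface form.
    """

    name: str
    n_patients: int
    emission: Mapping[str, float]
    negation_rate: float | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    features: FeatureSet
    class_specs: tuple[ClassSpec, ...]
    phrase_banks: Mapping[str, PhraseBank]
    notes_per_patient: tuple[int, int] = (3, 6)
    sentences_per_note: tuple[int, int] = (4, 8)
    filler_vocabulary: tuple[str, ...] = DEFAULT_FILLER_VOCABULARY
    negation_rate: float = 0.0
    decoy_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_specs:
            raise ValueError("at least one class required")
        for spec in self.class_specs:
            for name, p in spec.emission.items():
                if name not in self.features.names:
                    raise ValueError(f"class {spec.name!r}: unknown feature {name!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"class {spec.name!r}: emission prob {p} out of [0,1]")
            if spec.negation_rate is not None and not (0.0 <= spec.negation_rate <= 1.0):
                raise ValueError("negation_rate out of [0,1]")
        if not (0.0 <= self.negation_rate <= 1.0):
            raise ValueError("negation_rate out of [0,1]")


@dataclass
class GroundTruth:
    """Planted per-feature match counts, exact by construction.

    ``note_counts[patient_id][k]`` is the planted count vector (aligned with
    ``feature_names``) of the patient's k-th note in note_id order;
    ``labels[patient_id]`` is the true class.
    """

    feature_names: list[str]
    labels: dict[str, str]
    note_counts: dict[str, list[np.ndarray]]

    def patient_mean(self, patient_id: str) -> np.ndarray:
        return np.stack(self.note_counts[patient_id]).mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "labels": self.labels,
            "note_counts": {
                pid: [v.tolist() for v in counts] for pid, counts in self.note_counts.items()
            },
        }


def _check_sentence_safe(phrase: str, kind: str) -> None:
    if not phrase or phrase != phrase.strip():
        raise GenerationError(f"{kind} phrase {phrase!r} is empty or has stray whitespace")
    if _FORBIDDEN_CHARS & set(phrase):
        raise GenerationError(
            f"{kind} phrase {phrase!r} contains sentence punctuation; "
            "phrases must stay within one sentence"
        )


def _phrase_counts(fs: FeatureSet, phrase: str) -> np.ndarray:
    # counted on the exact sentence string that will be emitted
    sentence = phrase + "."
    return np.array([count_matches(f, sentence) for f in fs], dtype=np.int64)


def _validate_banks(config: GeneratorConfig) -> dict[str, dict[str, np.ndarray]]:
    """Verify the phrase banks and precompute each phrase's match vector."""
    fs = config.features
    by_name = {f.name: f for f in fs}
    table: dict[str, dict[str, np.ndarray]] = {}
    for fname, bank in config.phrase_banks.items():
        if fname not in by_name:
            raise GenerationError(f"phrase bank for unknown feature {fname!r}")
        feat = by_name[fname]
        entry: dict[str, np.ndarray] = {}
        for phrase in bank.positives:
            _check_sentence_safe(phrase, "positive")
            if count_matches(feat, phrase + ".") == 0:
                raise GenerationError(
                    f"positive phrase {phrase!r} does not match feature {fname!r} "
                    f"({feat.pattern!r})"
                )
            entry[phrase] = _phrase_counts(fs, phrase)
        for phrase in bank.negated:
            _check_sentence_safe(phrase, "negated")
            if bank.negated_feature is not None:
                nf = by_name.get(bank.negated_feature)
                if nf is None:
                    raise GenerationError(
                        f"bank {fname!r}: negation feature {bank.negated_feature!r} not in set"
                    )
                if count_matches(nf, phrase + ".") == 0:
                    raise GenerationError(
                        f"negated phrase {phrase!r} does not match its negation feature "
                        f"{bank.negated_feature!r}"
                    )
            entry[phrase] = _phrase_counts(fs, phrase)
        for phrase in bank.decoys:
            _check_sentence_safe(phrase, "decoy")
            vec = _phrase_counts(fs, phrase)
            if vec.any():
                hit = fs.names[int(np.nonzero(vec)[0][0])]
                raise GenerationError(f"decoy {phrase!r} unexpectedly matches feature {hit!r}")
            entry[phrase] = vec
        table[fname] = entry
    return table


def _filler_sentence(rng: np.random.Generator, config: GeneratorConfig) -> str:
    k = int(rng.integers(3, 8))
    words = rng.choice(len(config.filler_vocabulary), size=k, replace=True)
    sentence = " ".join(config.filler_vocabulary[i] for i in words) + "."
    for f in config.features:
        if count_matches(f, sentence):
            raise GenerationError(
                f"filler sentence {sentence!r} matches feature {f.name!r}; "
                "choose a neutral filler vocabulary"
            )
    return sentence


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a labeled corpus plus its exact planted-count ground truth.

    Deterministic given ``config.seed``; the corpus round-trips through the
    corpus module's JSON dialect unchanged.
    """
    phrase_table = _validate_banks(config)
    rng = np.random.default_rng(config.seed)
    fs = config.features
    n_feat = len(fs)

    notes: list[ClinicalNote] = []
    labels: dict[str, str] = {}
    note_counts: dict[str, list[np.ndarray]] = {}

    pidx = 0
    for spec in config.class_specs:
        neg_rate = spec.negation_rate if spec.negation_rate is not None else config.negation_rate
        for _ in range(spec.n_patients):
            pid = f"p{pidx:04d}"
            pidx += 1
            labels[pid] = spec.name
            note_counts[pid] = []
            n_notes = int(rng.integers(config.notes_per_patient[0], config.notes_per_patient[1] + 1))
            for j in range(n_notes):
                n_slots = int(
                    rng.integers(config.sentences_per_note[0], config.sentences_per_note[1] + 1)
                )
                sentences: list[str] = []
                planted = np.zeros(n_feat, dtype=np.int64)
                for _ in range(n_slots):
                    sentences.append(_filler_sentence(rng, config))
                    for fname in fs.names:
                        p = spec.emission.get(fname, 0.0)
                        bank = config.phrase_banks.get(fname)
                        if bank is None or p == 0.0 or rng.random() >= p:
                            continue
                        use_negated = bank.negated and rng.random() < neg_rate
                        pool = bank.negated if use_negated else bank.positives
                        phrase = pool[int(rng.integers(len(pool)))]
                        sentences.append(phrase + ".")
                        planted += phrase_table[fname][phrase]
                    if config.decoy_rate and rng.random() < config.decoy_rate:
                        decoy_pool = [
                            (fname, d)
                            for fname, bank in config.phrase_banks.items()
                            for d in bank.decoys
                        ]
                        if decoy_pool:
                            fname, decoy = decoy_pool[int(rng.integers(len(decoy_pool)))]
                            sentences.append(decoy + ".")
                            # decoys verified match-free: no count contribution
                text = " ".join(sentences)
                notes.append(
                    ClinicalNote(
                        note_id=f"{pid}-n{j:02d}",
                        patient_id=pid,
                        text=text,
                        metadata={LABEL_KEY: spec.name},
                    )
                )
                note_counts[pid].append(planted)

    corpus = corpus_from_notes(notes, LABEL_KEY)
    truth = GroundTruth(list(fs.names), labels, note_counts)
    return corpus, truth


# --- benchmark scenarios ----------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A ready-made corpus + feature set with a stated expected difficulty."""

    name: str
    corpus: Corpus
    features: FeatureSet
    truth: GroundTruth
    difficulty: str
    alt_features: FeatureSet | None = None  # e.g. the keyword-only contrast set


def _balanced_config(seed: int, case_rate: float = 0.3, control_rate: float = 0.01) -> GeneratorConfig:
    fs = FeatureSet(
        (
            FeatureDefinition("pelvic_pain", r"pelvic pain"),
            FeatureDefinition("vaginal_bleeding", r"(vaginal|heavy) bleeding"),
        )
    )
    banks = {
        "pelvic_pain": PhraseBank(
            positives=(
                "reports worsening pelvic pain",
                "chronic pelvic pain noted on exam",
                "pelvic pain persists despite analgesia",
            ),
            decoys=("pelvic exam deferred", "back pain improving"),
        ),
        "vaginal_bleeding": PhraseBank(
            positives=("heavy bleeding for several days", "intermittent vaginal bleeding reported"),
            decoys=("gums bleeding after flossing",),
        ),
    }
    return GeneratorConfig(
        features=fs,
        class_specs=(
            ClassSpec("case", 25, {"pelvic_pain": case_rate, "vaginal_bleeding": 0.05}),
            ClassSpec("noncase", 25, {"pelvic_pain": control_rate, "vaginal_bleeding": 0.05}),
        ),
        phrase_banks=banks,
        seed=seed,
    )


def _imbalanced_config(seed: int) -> GeneratorConfig:
    fs = FeatureSet(
        (
            FeatureDefinition("situs_anomaly", r"(s|S)itus (inversus|ambiguous)|(d|D)extrocardia"),
            FeatureDefinition("ear_tubes", r"(E|e)ar tubes?|tympanoplasty"),
        )
    )
    banks = {
        "situs_anomaly": PhraseBank(
            positives=("imaging consistent with situs inversus", "dextrocardia on chest film"),
            decoys=("normal cardiac situs",),
        ),
        "ear_tubes": PhraseBank(
            positives=("ear tubes placed in infancy", "status post tympanoplasty"),
            decoys=("ears clear bilaterally",),
        ),
    }
    return GeneratorConfig(
        features=fs,
        class_specs=(
            ClassSpec("case", 10, {"situs_anomaly": 0.06, "ear_tubes": 0.10}),
            ClassSpec("control", 100, {"situs_anomaly": 0.0, "ear_tubes": 0.02}),
        ),
        phrase_banks=banks,
        notes_per_patient=(1, 3),
        sentences_per_note=(3, 6),
        seed=seed,
    )


def negation_feature_sets() -> tuple[FeatureSet, FeatureSet]:
    """(negation-aware, keyword-only) feature sets for the negation scenario."""
    keyword = FeatureDefinition("pelvic_pain", r"pelvic pain")
    denies = FeatureDefinition("denies_pelvic_pain", r"(denies|no).{0,35}pelvic pain")
    return FeatureSet((keyword, denies)), FeatureSet((keyword,))


def _negation_config(seed: int, rate: float = 0.3) -> GeneratorConfig:
    aware, _ = negation_feature_sets()
    banks = {
        "pelvic_pain": PhraseBank(
            positives=(
                "reports worsening pelvic pain",
                "pelvic pain with menses",
            ),
            negated=(
                "denies any pelvic pain today",
                "no cramping or pelvic pain",
            ),
            negated_feature="denies_pelvic_pain",
            decoys=("pelvic exam deferred",),
        )
    }
    return GeneratorConfig(
        features=aware,
        class_specs=(
            ClassSpec("symptomatic", 25, {"pelvic_pain": rate}, negation_rate=0.0),
            ClassSpec("asymptomatic", 25, {"pelvic_pain": rate}, negation_rate=1.0),
        ),
        phrase_banks=banks,
        seed=seed,
    )


def make_benchmark_suite(seed: int) -> dict[str, Scenario]:
    """Three study-shaped scenarios with matched feature sets.

    * ``balanced``: two classes of 25 patients, strong emission gap (0.3 vs
      0.01) — linearly separable in expectation; easy.
    * ``imbalanced``: ~1:10 case:control with a weak case signal — high
      specificity is cheap, sensitivity degrades; moderate/hard.
    * ``negation``: labels depend on "denies pelvic pain" vs "pelvic pain";
      trivial with a negation-aware feature set (``features``), near chance
      with the keyword-only contrast set (``alt_features``).
    """
    scenarios: dict[str, Scenario] = {}

    cfg = _balanced_config(seed)
    corpus, truth = generate_corpus(cfg)
    scenarios["balanced"] = Scenario("balanced", corpus, cfg.features, truth, "easy")

    cfg = _imbalanced_config(seed + 1)
    corpus, truth = generate_corpus(cfg)
    scenarios["imbalanced"] = Scenario("imbalanced", corpus, cfg.features, truth, "moderate")

    cfg = _negation_config(seed + 2)
    corpus, truth = generate_corpus(cfg)
    aware, keyword_only = negation_feature_sets()
    scenarios["negation"] = Scenario(
        "negation", corpus, aware, truth, "easy with negation features", alt_features=keyword_only
    )
    return scenarios


def negation_corpus(seed: int) -> tuple[Corpus, FeatureSet, FeatureSet]:
    """Fresh negation-scenario corpus plus (aware, keyword-only) feature sets."""
    cfg = _negation_config(seed)
    corpus, _ = generate_corpus(cfg)
    aware, keyword_only = negation_feature_sets()
    return corpus, aware, keyword_only


def balanced_corpus(seed: int, case_rate: float = 0.3, control_rate: float = 0.01) -> tuple[Corpus, FeatureSet]:
    """Fresh balanced-scenario corpus with a configurable emission gap."""
    cfg = _balanced_config(seed, case_rate, control_rate)
    corpus, _ = generate_corpus(cfg)
    return corpus, cfg.features
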