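"""Morphological analyses of word forms.

Words are represented by sets of :class:`MorphAnalysis` objects — one per
morphological reading — so that context-free ambiguity (e.g. a noun form
syncretic between nominative and accusative singular) is preserved rather
than resolved.  Matching between a candidate continuation and a target word
is *permissive*: an ambiguous form matches if any of its readings does.

The inventory follows the word classes distinguished in the predictability
analyses: nouns, finite verbs, infinitives, adjectives, adverbs, numerals,
personal pronouns, prepositions, conjunctions, particles, plus an ``other``
bucket used for unknown forms.  Nouns carry gender/number/case; finite verbs
carry tense plus number and, depending on tense, person (present/future) or
gender (past) — the core agreement system of Russian inflection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, Mapping

__all__ = [
    "WORD_CLASSES",
    "FEATURE_VALUES",
    "MorphAnalysis",
    "MorphLexicon",
    "UNKNOWN_ANALYSIS",
    "analyze",
    "class_match",
    "feature_match",
    "read_lexicon",
    "write_lexicon",
]

WORD_CLASSES = (
    "noun",
    "verb_finite",
    "verb_infinitive",
    "adjective",
    "adverb",
    "numeral",
    "personal_pronoun",
    "preposition",
    "conjunction",
    "particle",
    "other",
)

FEATURE_VALUES: Mapping[str, tuple] = {
    "gender": ("m", "f", "n"),
    "number": ("sg", "pl"),
    "case": ("nom", "gen", "dat", "acc", "ins", "loc"),
    "tense": ("past", "present", "future"),
    "person": ("1", "2", "3"),
}

# Feature keys each word class may carry.  Finite verbs are additionally
# constrained by tense: person only in present/future, gender only in past.
_CLASS_FEATURES = {
    "noun": frozenset({"gender", "number", "case"}),
    "verb_finite": frozenset({"tense", "number", "person", "gender"}),
}


class MorphologyError(ValueError):
    """Invalid word class, feature key or feature value."""


@dataclass(frozen=True)
class MorphAnalysis:
    """One morphological reading: a word class plus a partial feature map."""

    word_class: str
    features: FrozenSet[tuple] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.word_class not in WORD_CLASSES:
            raise MorphologyError(f"unknown word class: {self.word_class!r}")
        feats = dict(self.features) if not isinstance(self.features, Mapping) else dict(self.features)
        if isinstance(self.features, Mapping):
            object.__setattr__(self, "features", frozenset(feats.items()))
        allowed = _CLASS_FEATURES.get(self.word_class, frozenset())
        for key, value in feats.items():
            if key not in FEATURE_VALUES:
                raise MorphologyError(f"unknown feature key: {key!r}")
            if key not in allowed:
                raise MorphologyError(
                    f"feature {key!r} not permitted for word class {self.word_class!r}"
                )
            if str(value) not in FEATURE_VALUES[key]:
                raise MorphologyError(f"bad value {value!r} for feature {key!r}")
        if self.word_class == "verb_finite":
            tense = feats.get("tense")
            if tense in ("present", "future") and "gender" in feats:
                raise MorphologyError("present/future finite verbs do not mark gender")
            if tense == "past" and "person" in feats:
                raise MorphologyError("past-tense finite verbs do not mark person")
            if tense is None and ("person" in feats or "gender" in feats):
                raise MorphologyError("person/gender on a finite verb require a tense")

    def feature(self, key: str):
        """Value of ``key`` in this reading, or None if undefined."""
        return dict(self.features).get(key)


#: Analysis assigned to forms absent from the lexicon.
UNKNOWN_ANALYSIS = MorphAnalysis("other")


class MorphLexicon:
    """Static form → analyses lookup table.

    Lookup never fails: forms that are not listed map to the designated
    unknown analysis (word class ``other``, no features).
    """

    def __init__(self, entries: Mapping[str, Iterable[MorphAnalysis]] | None = None):
        self._entries: dict[str, frozenset[MorphAnalysis]] = {}
        for form, analyses in (entries or {}).items():
            self.add(form, analyses)

    def add(self, form: str, analyses: Iterable[MorphAnalysis]) -> None:
        aset = frozenset(analyses)
        if not aset:
            raise MorphologyError(f"form {form!r} must have at least one analysis")
        key = form.strip().lower()
        self._entries[key] = self._entries.get(key, frozenset()) | aset

    def __contains__(self, form: str) -> bool:
        return form.strip().lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def forms(self):
        return self._entries.keys()

    def lookup(self, form: str) -> frozenset[MorphAnalysis]:
        return self._entries.get(form.strip().lower(), frozenset({UNKNOWN_ANALYSIS}))


def analyze(form: str, lexicon: MorphLexicon) -> frozenset[MorphAnalysis]:
    """All morphological readings of ``form`` under ``lexicon``.

    Ambiguous forms return every reading; unlisted forms return the unknown
    analysis.  An empty (or whitespace-only) form is an error.
    """
    if not form or not form.strip():
        raise MorphologyError("empty word form")
    return lexicon.lookup(form)


def class_match(candidate: Iterable[MorphAnalysis], target: Iterable[MorphAnalysis]) -> bool:
    """True iff some candidate reading shares a word class with some target reading."""
    cand = list(candidate)
    targ = list(target)
    if not cand or not targ:
        raise MorphologyError("analysis sets must be non-empty")
    cand_classes = {a.word_class for a in cand}
    return any(a.word_class in cand_classes for a in targ)


def feature_match(
    candidate: Iterable[MorphAnalysis],
    target: Iterable[MorphAnalysis],
    feature: str,
) -> bool:
    """True iff a candidate and a target reading agree on ``feature``.

    Agreement is conditioned on word class: both readings must define the
    feature with equal value *and* belong to the same word class (a noun's
    ``sg`` never matches a verb's ``sg``).  Ambiguity is permissive — any
    pair of readings suffices.
    """
    if feature not in FEATURE_VALUES:
        raise MorphologyError(f"unknown feature name: {feature!r}")
    cand = list(candidate)
    targ = list(target)
    if not cand or not targ:
        raise MorphologyError("analysis sets must be non-empty")
    for a in cand:
        va = a.feature(feature)
        if va is None:
            continue
        for b in targ:
            if b.word_class == a.word_class and b.feature(feature) == va:
                return True
    return False


_COLUMNS = ["form", "word_class", "gender", "number", "case", "tense", "person"]


def read_lexicon(path: str | Path) -> MorphLexicon:
    """Read a lexicon TSV (one row per analysis; empty cell = undefined)."""
    lex = MorphLexicon()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            feats = {k: row[k] for k in ("gender", "number", "case", "tense", "person")
                     if row.get(k)}
            lex.add(row["form"], [MorphAnalysis(row["word_class"], frozenset(feats.items()))])
    return lex


def write_lexicon(lexicon: MorphLexicon, path: str | Path) -> None:
    """Write a lexicon TSV with deterministic (sorted) row order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for form in sorted(lexicon.forms):
            for a in sorted(lexicon.lookup(form),
                            key=lambda a: (a.word_class, sorted(a.features))):
                feats = dict(a.features)
                writer.writerow([form, a.word_class] +
                                [feats.get(k, "") for k in
                                 ("gender", "number", "case", "tense", "person")])
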