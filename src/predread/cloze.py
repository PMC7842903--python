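"""Aggregation of cumulative cloze responses into lexical probabilities.

In the cumulative cloze task participants guess every word of a sentence in
turn, seeing the actual word after each guess, so each stimulus word
accumulates a multiset of typed guesses.  The lexical probability of a
target word is the share of guesses that match it orthographically (exact
form match after normalization).  Zero counts are smoothed to
``1/(2·n_guesses)``; symmetric to that, an all-correct word is capped at
``1 − 1/(2·n_guesses)`` so the logit transform stays finite.

Sentence-initial words receive no record: with no preceding context the
task gives no information about them.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "ClozeResponseSet",
    "ClozeRecord",
    "normalize_response",
    "smooth_zero",
    "cap_one",
    "lexical_probability",
    "response_shares",
    "read_responses",
    "write_records",
    "aggregate_responses",
]


class ClozeError(ValueError):
    pass


def normalize_response(form: str) -> str:
    """Lower-case + Unicode NFC.  Typo correction is assumed done upstream."""
    return unicodedata.normalize("NFC", form.strip().lower())


@dataclass(frozen=True)
class ClozeResponseSet:
    """All guesses for one stimulus word."""

    word_id: Tuple[object, int]  # (sentence_id, position)
    responses: Tuple[str, ...]

    @property
    def n_guesses(self) -> int:
        return len(self.responses)

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.responses:
            out[r] = out.get(r, 0) + 1
        return out


@dataclass(frozen=True)
class ClozeRecord:
    word_id: Tuple[object, int]
    p_lexical: float
    smoothed: bool
    n_guesses: int


def smooth_zero(n_guesses: int) -> float:
    """Smoothed probability for a word no participant guessed: 1/(2n)."""
    if n_guesses < 1:
        raise ClozeError("n_guesses must be >= 1")
    return 1.0 / (2.0 * n_guesses)


def cap_one(n_guesses: int) -> float:
    """Cap for a word every participant guessed: 1 - 1/(2n)."""
    if n_guesses < 1:
        raise ClozeError("n_guesses must be >= 1")
    return 1.0 - 1.0 / (2.0 * n_guesses)


def lexical_probability(rs: ClozeResponseSet, target_form: str) -> ClozeRecord:
    """Share of guesses orthographically matching the target.

    Zero matches give the smoothed value 1/(2n) with ``smoothed=True``;
    a full house is capped at 1 − 1/(2n) to keep the logit finite.
    """
    if rs.n_guesses < 1:
        raise ClozeError(f"empty response set for word {rs.word_id}")
    target = normalize_response(target_form)
    hits = sum(1 for r in rs.responses if r == target)
    n = rs.n_guesses
    if hits == 0:
        return ClozeRecord(rs.word_id, smooth_zero(n), True, n)
    p = hits / n
    if p >= 1.0:
        p = cap_one(n)
    return ClozeRecord(rs.word_id, p, False, n)


def response_shares(rs: ClozeResponseSet) -> Dict[str, float]:
    """Raw probability mass over the distinct guessed forms (sums to 1)."""
    n = rs.n_guesses
    return {form: c / n for form, c in sorted(rs.counts().items())}


def read_responses(path: str | Path) -> Dict[Tuple[object, int], ClozeResponseSet]:
    """Read a responses TSV (participant_id, sentence_id, position, response)."""
    buckets: Dict[Tuple[object, int], List[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["sentence_id"], int(row["position"]))
            buckets.setdefault(key, []).append(normalize_response(row["response"]))
    return {key: ClozeResponseSet(key, tuple(resp)) for key, resp in sorted(buckets.items())}


def aggregate_responses(
    response_sets: Mapping[Tuple[object, int], ClozeResponseSet],
    stimuli: Iterable[Mapping],
) -> List[ClozeRecord]:
    """Aggregate responses against stimulus targets.

    ``stimuli`` rows need sentence_id, position, form and is_first;
    sentence-initial words are skipped and carry no record.
    """
    records: List[ClozeRecord] = []
    for row in stimuli:
        if int(row["is_first"]):
            continue
        key = (row["sentence_id"], int(row["position"]))
        rs = response_sets.get(key)
        if rs is None:
            raise ClozeError(f"no responses for stimulus word {key}")
        records.append(lexical_probability(rs, row["form"]))
    return records


def write_records(records: Iterable[ClozeRecord], targets: Mapping, path: str | Path) -> None:
    """Write the output TSV: sentence_id, position, target, n_guesses, p_lexical, smoothed."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sentence_id", "position", "target", "n_guesses",
                         "p_lexical", "smoothed"])
        for rec in records:
            sid, pos = rec.word_id
            writer.writerow([sid, pos, targets.get(rec.word_id, ""), rec.n_guesses,
                             repr(rec.p_lexical), int(rec.smoothed)])
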