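"""Fixation-duration measures and assembly of the per-word analysis table.

Four standard measures are derived per (participant, word) from the raw
fixation sequence of a trial:

* **FFD** — duration of the first fixation on the word;
* **GD** — gaze duration: sum of the first-pass fixations, i.e. the maximal
  initial run of consecutive fixations on the word starting at its first
  fixation, ending as soon as any other word is fixated;
* **TT** — total reading time: sum of all fixations on the word;
* **SFD** — single fixation duration: defined only when the word received
  exactly one fixation in the whole trial (then SFD = FFD = GD = TT).

Words that are never fixated have all measures undefined.  The analysis
table pairs each included word's measures with the predictors used in the
duration models: length (centered and scaled), log10 frequency and logit
probability for the previous, current and next words, plus oculomotor
covariates for the current word.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Fixation",
    "compute_measures",
    "fixations_from_frame",
    "trial_measures_frame",
    "apply_exclusions",
    "log_frequency",
    "build_table",
    "MEASURES",
]

MEASURES = ("SFD", "FFD", "GD", "TT")

#: Frequency floor: zero-count forms are treated as 0.5 per million.
FREQ_FLOOR_PER_MILLION = 0.5


class ReadingMeasuresError(ValueError):
    pass


@dataclass(frozen=True)
class Fixation:
    participant_id: str
    sentence_id: object
    fixation_index: int
    word_position: int  # 1-based within sentence
    duration: float  # ms
    landing_position: int = 0  # 0-based characters from word start
    incoming_saccade_amplitude: float = 0.0  # characters


def compute_measures(fixations: Sequence[Fixation]) -> Dict[int, dict]:
    """Per-word measures for one trial.

    ``fixations`` must be sorted by fixation_index.  Returns a map
    word_position → dict(SFD, FFD, GD, TT, fixated, n_fixations,
    landing, sacc_amp); unfixated words are simply absent.
    """
    order = [f.fixation_index for f in fixations]
    if order != sorted(order):
        raise ReadingMeasuresError("fixations must be sorted by fixation_index")
    out: Dict[int, dict] = {}
    for i, fix in enumerate(fixations):
        if fix.duration <= 0:
            raise ReadingMeasuresError(
                f"non-positive fixation duration at index {fix.fixation_index}")
        w = fix.word_position
        rec = out.get(w)
        if rec is None:
            rec = out[w] = {
                "FFD": fix.duration, "GD": fix.duration, "TT": fix.duration,
                "n_fixations": 1, "fixated": True,
                "landing": fix.landing_position,
                "sacc_amp": fix.incoming_saccade_amplitude,
                "_first_pass_open": True, "_first_index": i,
            }
        else:
            rec["TT"] += fix.duration
            rec["n_fixations"] += 1
            # First pass continues only through consecutive fixations.
            if rec["_first_pass_open"] and i == rec["_last_index"] + 1:
                rec["GD"] += fix.duration
            else:
                rec["_first_pass_open"] = False
        rec["_last_index"] = i
    for rec in out.values():
        rec["SFD"] = rec["FFD"] if rec["n_fixations"] == 1 else float("nan")
        for key in ("_first_pass_open", "_first_index", "_last_index"):
            rec.pop(key, None)
    return out


def fixations_from_frame(df: pd.DataFrame) -> List[Fixation]:
    """Convert a fixations table (TSV layout) into Fixation records."""
    return [Fixation(str(r.participant_id), r.sentence_id, int(r.fixation_index),
                     int(r.word_position), float(r.duration_ms),
                     int(r.landing_char), float(r.saccade_amp_char))
            for r in df.itertuples()]


def trial_measures_frame(fixations: Iterable[Fixation]) -> pd.DataFrame:
    """Measures for all trials, one row per (participant, sentence, word)."""
    trials: Dict[Tuple[str, object], List[Fixation]] = {}
    for f in fixations:
        trials.setdefault((f.participant_id, f.sentence_id), []).append(f)
    rows = []
    for (pid, sid), fixs in sorted(trials.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        fixs = sorted(fixs, key=lambda f: f.fixation_index)
        for pos, rec in sorted(compute_measures(fixs).items()):
            rows.append({"participant_id": pid, "sentence_id": sid, "position": pos,
                         **rec})
    return pd.DataFrame(rows)


def apply_exclusions(stimuli: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Word-exclusion rules per analysis stage.

    ``correlation`` drops sentence-initial words (no context to predict
    from); ``eyetracking`` additionally drops sentence-final words
    (end-of-sentence wrap-up).
    """
    if stage == "correlation":
        keep = stimuli["is_first"].astype(int) == 0
    elif stage == "eyetracking":
        keep = (stimuli["is_first"].astype(int) == 0) & (stimuli["is_last"].astype(int) == 0)
    else:
        raise ReadingMeasuresError(f"unknown stage {stage!r}")
    return stimuli[keep]


def log_frequency(freq_per_million: float) -> float:
    """log10 frequency with a 0.5-per-million floor for zero counts."""
    return math.log10(max(freq_per_million, FREQ_FLOOR_PER_MILLION))


_SOURCES = ("cloze", "corpus")
_FEATURES = ("gender", "number", "case", "tense", "person")


def build_table(measures: pd.DataFrame,
                predictability: pd.DataFrame,
                frequencies: Mapping[str, float],
                stimuli: pd.DataFrame,
                sources: Sequence[str] = _SOURCES) -> pd.DataFrame:
    """Assemble the per-(participant, word) analysis table.

    Neighbour predictors are taken at the raw sentence positions n−1/n+1:
    exclusion rules apply to the dependent word only.  A row whose required
    neighbour predictor does not exist *because that neighbour is
    sentence-initial* (initial words carry no cloze record) is dropped —
    identically for every source, so cloze and corpus model rows stay
    aligned.  Any other missing predictor raises, naming the word.
    Word lengths are centered and scaled over the included rows.
    """
    word = stimuli[["sentence_id", "position", "form", "is_first", "is_last"]].copy()
    word["target_tense"] = stimuli["target_tense"] if "target_tense" in stimuli else ""
    word["base_form"] = stimuli["base_form"].astype(int) if "base_form" in stimuli else 0
    word["len"] = word["form"].str.len().astype(float)
    word["logfreq"] = word["form"].map(
        lambda f: log_frequency(float(frequencies.get(f, 0.0))))
    pcols = [c for c in predictability.columns
             if c.startswith("q_") or c == "target_class"]
    word = word.merge(predictability[["sentence_id", "position"] + pcols],
                      on=["sentence_id", "position"], how="left")

    included = apply_exclusions(stimuli, "eyetracking")[["sentence_id", "position"]]
    table = measures.merge(included, on=["sentence_id", "position"], how="inner")
    table = table.rename(columns={"participant_id": "participant",
                                  "sentence_id": "sentence"})

    def neighbour(offset: int, tag: str, cols) -> None:
        nonlocal table
        shifted = word.rename(columns=dict(cols))
        shifted = shifted[["sentence_id", "position", "is_first"] +
                          [v for _, v in cols]]
        shifted = shifted.rename(columns={"is_first": f"_is_first_{tag}"})
        shifted["position"] = shifted["position"] - offset
        table = table.merge(shifted.rename(columns={"sentence_id": "sentence"}),
                            on=["sentence", "position"], how="left")

    lex_cols = [f"q_lex_{src}" for src in sources]
    neighbour(-1, "prev", [("form", "_form_prev"), ("len", "len_prev"),
                           ("logfreq", "logfreq_prev")] +
              [(c, f"q_lex_prev_{src}") for c, src in zip(lex_cols, sources)])
    neighbour(0, "cur", [("form", "word"), ("len", "len_cur"),
                         ("logfreq", "logfreq_cur"), ("target_class", "target_class"),
                         ("target_tense", "target_tense"), ("base_form", "base_form")] +
              [(c, f"q_lex_cur_{src}") for c, src in zip(lex_cols, sources)] +
              [(f"q_class_{src}", f"q_class_cur_{src}") for src in sources] +
              [(f"q_{feat}_{src}", f"q_{feat}_{src}")
               for src in sources for feat in _FEATURES
               if f"q_{feat}_{src}" in word.columns])
    neighbour(1, "next", [("len", "len_next"), ("logfreq", "logfreq_next")] +
              [(c, f"q_lex_next_{src}") for c, src in zip(lex_cols, sources)] +
              [(f"q_class_{src}", f"q_class_next_{src}") for src in sources])

    # Rows whose previous word is sentence-initial lack its cloze record by
    # construction; drop them for every source alike.  Any other missing
    # lexical or class probability is a data defect.
    prev_initial = table["_is_first_prev"].fillna(0).astype(int) == 1
    for src in sources:
        for tag, neighbour_initial in (("prev", prev_initial),
                                       ("cur", False), ("next", False)):
            bad = table[f"q_lex_{tag}_{src}"].isna() & ~prev_initial
            if bad.any():
                offset = {"prev": -1, "cur": 0, "next": 1}[tag]
                r = table[bad].iloc[0]
                raise ReadingMeasuresError(
                    f"missing {src} probability for word "
                    f"{(r['sentence'], int(r['position']) + offset)}")
        for tag, offset in (("cur", 0), ("next", 1)):
            bad = table[f"q_class_{tag}_{src}"].isna() & ~prev_initial
            if bad.any():
                r = table[bad].iloc[0]
                raise ReadingMeasuresError(
                    f"missing {src} class probability for word "
                    f"{(r['sentence'], int(r['position']) + offset)}")
    table = table[~prev_initial].drop(
        columns=[c for c in table.columns if c.startswith("_")]).reset_index(drop=True)
    for feat in _FEATURES:
        for src in sources:
            if f"q_{feat}_{src}" not in table.columns:
                table[f"q_{feat}_{src}"] = float("nan")
    table["sacc_amp"] = table["sacc_amp"].astype(float)
    table["landing"] = table["landing"].astype(float)
    if len(table):
        for col in ("len_prev", "len_cur", "len_next"):
            vals = table[col].astype(float)
            sd = vals.std(ddof=1)
            table[col] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    return table
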