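"""Seeded synthetic datasets with known ground truth for the whole pipeline.

The generator emulates the structure of a reading-predictability study:

* a morphologically tagged lexicon of pseudo-word forms;
* stimulus sentences sampled from a first-order Markov chain whose exact
  conditional distributions are retained as ground truth;
* cumulative cloze guesses drawn from those true distributions, optionally
  reweighted against long words (typing-effort bias);
* corpus-model distributions obtained by Dirichlet perturbation of the
  truth (estimation error; infinite concentration recovers the truth);
* fixation sequences whose log gaze durations follow a lognormal
  hierarchical model with known coefficients and variance components.

Everything is driven by one root seed through named substreams, so each
stage regenerates independently and byte-identically.

The generator mirrors the statistical skeleton of real data, not its
linguistics: sentences are not grammatical, and fixation sequences come
from a simple skip/refixate/regress scheme rather than an oculomotor
model.  Passing tests on these data demonstrates correctness of the
pipeline's computations, not psycholinguistic validity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cloze import ClozeResponseSet
from .language_model import DistributionTable, ProbDistribution
from .morphology import FEATURE_VALUES, MorphAnalysis, MorphLexicon, analyze, write_lexicon
from .predictability import predictability_table

__all__ = [
    "DEFAULT_CLASS_MIX",
    "SimConfig",
    "ChainTruth",
    "SyntheticBundle",
    "rng_for",
    "make_lexicon",
    "make_stimuli_and_truth",
    "sample_cloze",
    "distort_distribution",
    "make_frequencies",
    "simulate_reading",
    "make_bundle",
    "write_bundle",
]

# Word-class mixture loosely matching written-corpus class shares
# (nouns ~37%, adjectives ~14%, the rest spread over the inventory).
DEFAULT_CLASS_MIX: Dict[str, float] = {
    "noun": 0.37, "adjective": 0.14, "verb_finite": 0.15,
    "verb_infinitive": 0.04, "adverb": 0.05, "personal_pronoun": 0.06,
    "preposition": 0.10, "conjunction": 0.05, "particle": 0.03,
    "numeral": 0.01,
}

_SUBSTREAMS = {"lexicon": 1, "stimuli": 2, "cloze": 3, "corpus": 4,
               "reading": 5, "frequencies": 6, "training": 7}


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named substream of the root seed."""
    return np.random.default_rng([int(seed), _SUBSTREAMS[name]])


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic bundle.

    Durations are generated as
    ``log(GD) = intercept + Σ beta[c]·x_c + u_participant + u_sentence +
    u_word + ε`` with the listed standard deviations (log-ms scale).
    """

    n_forms: int = 400
    ambiguity_rate: float = 0.15
    n_sentences: int = 144
    length_range: Tuple[int, int] = (5, 13)
    n_successors: int = 12
    n_participants: int = 30
    guess_base: int = 20                      # minimum guesses per word
    guess_mean_extra: float = 27.0            # mean guesses above the base
    guess_dispersion: float = 2.0             # negative-binomial r (spread)
    guess_max: int = 151
    cloze_bias: float = 0.0                   # long-word avoidance weight
    corpus_concentration: float = 200.0       # Dirichlet distortion of truth
    intercept: float = 5.4                    # exp(5.4) ≈ 221 ms
    # beta keys name predictability-table columns (per-word, e.g.
    # "q_lex_cloze"); the coefficient applies to the currently read word.
    beta: Dict[str, float] = field(default_factory=lambda: {"q_lex_cloze": -0.05})
    sd_participant: float = 0.12
    sd_sentence: float = 0.06
    sd_word: float = 0.08
    sd_residual: float = 0.30
    skip_base: float = -2.0                   # logit of skip probability
    skip_slope: float = 0.6                   # increases with predictability
    skip_on: Optional[str] = "q_lex_cloze"
    refix_base: float = -1.8
    refix_len_slope: float = 0.12
    regress_prob: float = 0.12
    n_training_sentences: int = 400


_CONSONANTS = list("bdfgklmnprstvz")
_VOWELS = list("aeiou")


def _sample_form(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(1, 5))
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(n_syll)) + (rng.choice(_CONSONANTS)
                                             if rng.random() < 0.5 else "")


def _sample_analysis(rng: np.random.Generator, word_class: str) -> MorphAnalysis:
    feats: Dict[str, str] = {}
    if word_class == "noun":
        feats = {"gender": rng.choice(FEATURE_VALUES["gender"]),
                 "number": rng.choice(FEATURE_VALUES["number"]),
                 "case": rng.choice(FEATURE_VALUES["case"])}
    elif word_class == "verb_finite":
        tense = rng.choice(FEATURE_VALUES["tense"])
        feats = {"tense": tense, "number": rng.choice(FEATURE_VALUES["number"])}
        if tense == "past":
            feats["gender"] = rng.choice(FEATURE_VALUES["gender"])
        else:
            feats["person"] = rng.choice(FEATURE_VALUES["person"])
    return MorphAnalysis(word_class, frozenset({(k, str(v)) for k, v in feats.items()}))


def make_lexicon(n_forms: int = 400, ambiguity_rate: float = 0.15,
                 class_mix: Optional[Mapping[str, float]] = None,
                 seed: int = 0) -> MorphLexicon:
    """Pseudo-word lexicon; each form may get a second reading (ambiguity)."""
    if not (0.0 <= ambiguity_rate <= 1.0):
        raise ValueError("ambiguity_rate must be in [0,1]")
    mix = dict(class_mix) if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    if not mix:
        raise ValueError("class_mix must be non-empty")
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes], float)
    probs = probs / probs.sum()
    rng = rng_for(seed, "lexicon")
    lex = MorphLexicon()
    seen = set()
    while len(seen) < n_forms:
        form = _sample_form(rng)
        if form in seen:
            continue
        seen.add(form)
        wc = str(rng.choice(classes, p=probs))
        analyses = [_sample_analysis(rng, wc)]
        if rng.random() < ambiguity_rate:
            # Second reading: for nouns a case-syncretic variant, otherwise
            # a reading in another word class.
            if wc == "noun" and rng.random() < 0.7:
                alt = _sample_analysis(rng, "noun")
            else:
                alt_wc = str(rng.choice(classes, p=probs))
                alt = _sample_analysis(rng, alt_wc)
            if alt not in analyses:
                analyses.append(alt)
        lex.add(form, analyses)
    return lex


class ChainTruth:
    """First-order generative chain with queryable conditional distributions."""

    def __init__(self, forms: List[str], initial: Dict[str, float],
                 transitions: Dict[str, Dict[str, float]]):
        self.forms = forms
        self.initial = initial
        self.transitions = transitions

    def distribution(self, prev_form: Optional[str]) -> Dict[str, float]:
        if prev_form is None:
            return self.initial
        return self.transitions[prev_form]

    def stimulus_distribution(self, stimuli: pd.DataFrame, sentence_id, position: int
                              ) -> Dict[str, float]:
        if position == 1:
            return self.initial
        prev = stimuli[(stimuli["sentence_id"] == sentence_id) &
                       (stimuli["position"] == position - 1)]["form"].iloc[0]
        return self.transitions[prev]


def _base_form_flag(form: str, lexicon: MorphLexicon) -> int:
    for a in analyze(form, lexicon):
        feats = dict(a.features)
        if a.word_class == "noun" and feats.get("case") == "nom":
            return 1
        if a.word_class in ("verb_infinitive", "adverb", "preposition",
                            "conjunction", "particle"):
            return 1
    return 0


def _target_tense(form: str, lexicon: MorphLexicon) -> str:
    for a in sorted(analyze(form, lexicon), key=lambda a: a.word_class):
        t = a.feature("tense")
        if t is not None:
            return t
    return ""


def make_stimuli_and_truth(n_sentences: int = 144,
                           length_range: Tuple[int, int] = (5, 13),
                           lexicon: Optional[MorphLexicon] = None,
                           seed: int = 0,
                           n_successors: int = 12) -> Tuple[pd.DataFrame, ChainTruth]:
    """Sample stimulus sentences from a seeded first-order chain.

    Lengths are uniform over ``length_range`` (the default 5–13 gives mean
    9).  The chain's exact conditional distributions are the ground truth
    against which cloze and corpus estimates can be checked.
    """
    lo, hi = length_range
    if not (2 <= lo <= hi <= 20):
        raise ValueError("length_range must lie within [2, 20]")
    if lexicon is None:
        lexicon = make_lexicon(seed=seed)
    rng = rng_for(seed, "stimuli")
    forms = sorted(lexicon.forms)
    k = len(forms)
    init_w = rng.dirichlet(np.full(k, 0.5))
    initial = {f: float(p) for f, p in zip(forms, init_w)}
    transitions: Dict[str, Dict[str, float]] = {}
    n_succ = min(n_successors, k)
    for f in forms:
        succ = rng.choice(k, size=n_succ, replace=False)
        w = rng.dirichlet(np.full(n_succ, 0.6))
        transitions[f] = {forms[j]: float(p) for j, p in
                          sorted(zip(succ, w), key=lambda t: forms[t[0]])}
    rows = []
    for s in range(n_sentences):
        sid = f"s{s + 1:03d}"
        length = int(rng.integers(lo, hi + 1))
        prev = None
        for pos in range(1, length + 1):
            dist = initial if prev is None else transitions[prev]
            cand = sorted(dist)
            p = np.array([dist[c] for c in cand])
            form = str(rng.choice(cand, p=p / p.sum()))
            rows.append({"sentence_id": sid, "position": pos, "form": form,
                         "is_first": int(pos == 1), "is_last": int(pos == length),
                         "base_form": _base_form_flag(form, lexicon),
                         "target_tense": _target_tense(form, lexicon)})
            prev = form
    return pd.DataFrame(rows), ChainTruth(forms, initial, transitions)


def sample_training_corpus(truth: ChainTruth, n_sentences: int,
                           length_range: Tuple[int, int], seed: int) -> List[List[str]]:
    """Extra sentences from the same chain, for n-gram training."""
    rng = rng_for(seed, "training")
    lo, hi = length_range
    out = []
    for _ in range(n_sentences):
        length = int(rng.integers(lo, hi + 1))
        sent, prev = [], None
        for _pos in range(length):
            dist = truth.distribution(prev)
            cand = sorted(dist)
            p = np.array([dist[c] for c in cand])
            prev = str(rng.choice(cand, p=p / p.sum()))
            sent.append(prev)
        out.append(sent)
    return out


def sample_cloze(truth: ChainTruth, stimuli: pd.DataFrame, seed: int = 0,
                 bias: float = 0.0, guess_base: int = 20,
                 guess_mean_extra: float = 27.0, guess_dispersion: float = 2.0,
                 guess_max: int = 151) -> pd.DataFrame:
    """Cloze guesses for every non-initial stimulus word.

    Each guess is drawn from the true next-word distribution reweighted by
    exp(−bias·len(word)) — a positive bias emulates the documented
    avoidance of long words in typed cloze responses.  The number of
    guesses per word is ``guess_base`` plus an overdispersed
    negative-binomial count (r = ``guess_dispersion``), clipped to
    ``guess_max``: self-selected participation makes per-word counts far
    more variable than a Poisson, and the defaults give counts in the
    20–151 range with mean ≈ 47.
    """
    rng = rng_for(seed, "cloze")
    rows = []
    for sid, sent in stimuli.groupby("sentence_id", sort=True):
        sent = sent.sort_values("position")
        prev = None
        for _, w in sent.iterrows():
            pos = int(w["position"])
            if pos > 1:
                dist = truth.distribution(prev)
                cand = sorted(dist)
                p = np.array([dist[c] for c in cand], float)
                if bias != 0.0:
                    p = p * np.exp(-bias * np.array([len(c) for c in cand]))
                p = p / p.sum()
                r = guess_dispersion
                extra = int(rng.negative_binomial(r, r / (r + guess_mean_extra)))
                n = min(guess_base + extra, guess_max)
                guesses = rng.choice(cand, size=n, p=p)
                for j, g in enumerate(guesses):
                    rows.append({"participant_id": f"c{j:03d}", "sentence_id": sid,
                                 "position": pos, "response": str(g)})
            prev = w["form"]
    return pd.DataFrame(rows)


def responses_to_sets(responses: pd.DataFrame) -> Dict[Tuple[str, int], ClozeResponseSet]:
    sets = {}
    for (sid, pos), grp in responses.groupby(["sentence_id", "position"], sort=True):
        key = (sid, int(pos))
        sets[key] = ClozeResponseSet(key, tuple(grp["response"]))
    return sets


def distort_distribution(truth: ChainTruth, stimuli: pd.DataFrame,
                         concentration: float = 200.0, seed: int = 0,
                         tail_eps: float = 1e-4) -> DistributionTable:
    """Corpus-model distributions: Dirichlet perturbation of the truth.

    Each true distribution (plus a small tail bucket) is resampled from
    Dirichlet(concentration · p); the expected value is the truth and the
    perturbation vanishes as concentration → ∞.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = rng_for(seed, "corpus")
    table = DistributionTable()
    for sid, sent in stimuli.groupby("sentence_id", sort=True):
        sent = sent.sort_values("position")
        prev = None
        for _, w in sent.iterrows():
            pos = int(w["position"])
            dist = truth.distribution(prev)
            cand = sorted(dist)
            p = np.array([dist[c] for c in cand], float)
            p = np.append(p * (1.0 - tail_eps), tail_eps)
            qv = rng.dirichlet(concentration * p)
            # Dirichlet can return exact zeros for tiny alphas; floor and
            # renormalize to keep every stored mass strictly positive.
            qv = np.maximum(qv, 1e-12)
            qv = qv / qv.sum()
            mass = {c: float(v) for c, v in zip(cand, qv[:-1])}
            table.put(sid, pos, ProbDistribution((sid, pos), mass, float(qv[-1])))
            prev = w["form"]
    return table


def make_frequencies(lexicon: MorphLexicon, seed: int = 0) -> Dict[str, float]:
    """Zipf-like per-million frequencies over the lexicon forms."""
    rng = rng_for(seed, "frequencies")
    forms = sorted(lexicon.forms)
    ranks = rng.permutation(len(forms)) + 1
    weights = 1.0 / ranks
    per_million = 1e6 * weights / weights.sum()
    return {f: float(x) for f, x in zip(forms, per_million)}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_reading(stimuli: pd.DataFrame, predictors: pd.DataFrame,
                     config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate fixation sequences with known lognormal ground truth.

    ``predictors`` is indexed by (sentence_id, position) and must contain
    every column named in ``config.beta``; NaN predictor values contribute
    nothing.  Per word, the first-pass gaze duration is lognormal around
    the linear predictor plus sampled intercepts; it is realized as one or
    two consecutive fixations, an optional later revisit adds to total
    time only.  Skipping becomes more likely as predictability rises.
    """
    rng = rng_for(seed, "reading")
    pred = predictors if isinstance(predictors.index, pd.MultiIndex) \
        else predictors.set_index(["sentence_id", "position"])
    forms = sorted(stimuli["form"].unique())
    sentences = sorted(stimuli["sentence_id"].unique())
    u_word = dict(zip(forms, rng.normal(0.0, config.sd_word, len(forms))))
    u_sent = dict(zip(sentences, rng.normal(0.0, config.sd_sentence, len(sentences))))

    sent_words = {sid: grp.sort_values("position")["form"].tolist()
                  for sid, grp in stimuli.groupby("sentence_id")}

    rows = []
    for i_part in range(config.n_participants):
        pid = f"p{i_part:03d}"
        u_p = rng.normal(0.0, config.sd_participant)
        for sid in sentences:
            words = sent_words[sid]
            starts = np.concatenate([[0], np.cumsum([len(w) + 1 for w in words])])
            events: List[Tuple[int, float, int]] = []  # (pos, duration, landing)
            pending_revisit: List[Tuple[int, float, int]] = []
            for pos in range(1, len(words) + 1):
                word = words[pos - 1]
                row = pred.loc[(sid, pos)] if (sid, pos) in pred.index else None
                eta = config.intercept + u_p + u_sent[sid] + u_word[word]
                qskip = None
                for col, b in config.beta.items():
                    val = row[col] if row is not None and col in row else np.nan
                    if not pd.isna(val):
                        eta += b * float(val)
                if config.skip_on is not None and row is not None \
                        and config.skip_on in row and not pd.isna(row[config.skip_on]):
                    qskip = float(row[config.skip_on])
                p_skip = _sigmoid(config.skip_base +
                                  (config.skip_slope * qskip if qskip is not None else 0.0))
                if pos > 1 and rng.random() < p_skip:
                    continue
                gd = float(np.exp(eta + rng.normal(0.0, config.sd_residual)))
                n_fix = 2 if rng.random() < _sigmoid(config.refix_base +
                                                     config.refix_len_slope * len(word)) else 1
                landing = int(rng.integers(0, len(word)))
                if n_fix == 1:
                    events.append((pos, gd, landing))
                else:
                    f = rng.uniform(0.35, 0.65)
                    events.append((pos, gd * f, landing))
                    events.append((pos, gd * (1.0 - f), int(rng.integers(0, len(word)))))
                if rng.random() < config.regress_prob:
                    pending_revisit.append((pos, gd * rng.uniform(0.2, 0.5),
                                            int(rng.integers(0, len(word)))))
            # Insert each revisit after the complete first-pass run of the
            # next later word, so the revisited word's first pass is
            # genuinely interrupted while no other word's run is split.  A
            # revisit with no later fixation to follow is dropped (it could
            # not be distinguished from a continued first pass).
            for rv_pos, rv_dur, rv_land in pending_revisit:
                insert_at = None
                seen_word = False
                for j, (pos, _d, _l) in enumerate(events):
                    if pos == rv_pos:
                        seen_word = True
                    elif seen_word and pos > rv_pos:
                        end = j
                        while end + 1 < len(events) and events[end + 1][0] == pos:
                            end += 1
                        insert_at = end + 1
                        break
                if insert_at is not None:
                    events.insert(insert_at, (rv_pos, rv_dur, rv_land))
            prev_char = None
            for idx, (pos, dur, landing) in enumerate(events, start=1):
                char = starts[pos - 1] + landing
                amp = float(abs(char - prev_char)) if prev_char is not None else 0.0
                prev_char = char
                rows.append({"participant_id": pid, "sentence_id": sid,
                             "fixation_index": idx, "word_position": pos,
                             "duration_ms": round(dur, 3), "landing_char": landing,
                             "saccade_amp_char": amp})
    return pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    """All artefacts of one synthetic study, mutually consistent."""

    config: SimConfig
    seed: int
    lexicon: MorphLexicon
    stimuli: pd.DataFrame
    truth: ChainTruth
    training_corpus: List[List[str]]
    responses: pd.DataFrame
    cloze_sets: Dict[Tuple[str, int], ClozeResponseSet]
    dist_table: DistributionTable
    frequencies: Dict[str, float]
    pred_table: pd.DataFrame
    fixations: pd.DataFrame


def make_bundle(config: Optional[SimConfig] = None, seed: int = 0) -> SyntheticBundle:
    """Generate a complete synthetic study from one root seed."""
    cfg = config or SimConfig()
    lexicon = make_lexicon(cfg.n_forms, cfg.ambiguity_rate, seed=seed)
    stimuli, truth = make_stimuli_and_truth(cfg.n_sentences, cfg.length_range,
                                            lexicon, seed=seed,
                                            n_successors=cfg.n_successors)
    training = sample_training_corpus(truth, cfg.n_training_sentences,
                                      cfg.length_range, seed)
    responses = sample_cloze(truth, stimuli, seed=seed, bias=cfg.cloze_bias,
                             guess_base=cfg.guess_base,
                             guess_mean_extra=cfg.guess_mean_extra,
                             guess_dispersion=cfg.guess_dispersion,
                             guess_max=cfg.guess_max)
    cloze_sets = responses_to_sets(responses)
    dist_table = distort_distribution(truth, stimuli, cfg.corpus_concentration, seed)
    frequencies = make_frequencies(lexicon, seed)
    pred = predictability_table(stimuli, cloze_sets, dist_table, lexicon)
    fixations = simulate_reading(stimuli, pred, cfg, seed)
    return SyntheticBundle(cfg, seed, lexicon, stimuli, truth, training,
                           responses, cloze_sets, dist_table, frequencies,
                           pred, fixations)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write every bundle artefact as plain text (byte-deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_lexicon(bundle.lexicon, out / "lexicon.tsv")
    _write_tsv(bundle.stimuli, out / "stimuli.tsv")
    with open(out / "corpus.txt", "w", encoding="utf-8") as fh:
        for sent in bundle.training_corpus:
            fh.write(" ".join(sent) + "\n")
    _write_tsv(bundle.responses, out / "responses.tsv")
    bundle.dist_table.to_jsonl(out / "provider.jsonl")
    freq = pd.DataFrame(sorted(bundle.frequencies.items()),
                        columns=["form", "freq_per_million"])
    _write_tsv(freq, out / "frequencies.tsv")
    _write_tsv(bundle.pred_table, out / "predictability.tsv")
    _write_tsv(bundle.fixations, out / "fixations.tsv")
    gt = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(bundle.config).items()},
        "seed": bundle.seed,
        "initial": {k: bundle.truth.initial[k] for k in sorted(bundle.truth.initial)},
        "transitions": {f: bundle.truth.transitions[f]
                        for f in sorted(bundle.truth.transitions)},
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
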