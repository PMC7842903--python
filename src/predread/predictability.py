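"""Lexical and morphosyntactic probabilities from cloze or corpus sources.

Both a cloze response set and a language-model distribution define a
probability mass function over candidate continuations; lexical, word-class
and morphological-feature probabilities are computed from that mass in
exactly the same way for both sources:

* lexical probability — mass on the exact target form;
* word-class probability — total mass on candidates whose analysis set
  class-matches the target (permissive over ambiguity);
* feature probability — total mass on candidates that feature-match the
  target (class-conditioned).

Probabilities are compared on the logit scale, q = 0.5·ln(p/(1−p)).
Zero/one masses are smoothed: cloze sources reuse the 1/(2n) rule and its
symmetric cap, corpus sources use a fixed floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cloze import ClozeResponseSet, cap_one, response_shares, smooth_zero
from .language_model import ProbDistribution
from .morphology import MorphLexicon, analyze, class_match, feature_match

__all__ = [
    "CORPUS_FLOOR",
    "logit_transform",
    "inverse_logit",
    "source_mass",
    "class_probability",
    "feature_probability",
    "target_features",
    "word_predictability",
    "predictability_table",
    "correlate",
    "cumulative_correlation_curve",
    "summarize_by_class",
    "CONTENT_CLASSES",
    "FUNCTION_CLASSES",
]

#: Floor/cap offset for corpus-derived class and feature probabilities.
CORPUS_FLOOR = 1e-9

CONTENT_CLASSES = ("noun", "verb_finite", "verb_infinitive", "adjective",
                   "adverb", "numeral")
FUNCTION_CLASSES = ("personal_pronoun", "preposition", "conjunction", "particle")


class PredictabilityError(ValueError):
    pass


def logit_transform(p: float) -> float:
    """Half-logit q = 0.5·ln(p/(1−p)); strictly increasing, 0 at p = 0.5."""
    if not (0.0 < p < 1.0):
        raise PredictabilityError(f"probability must be in (0,1), got {p}")
    return 0.5 * math.log(p / (1.0 - p))


def inverse_logit(q: float) -> float:
    return 1.0 / (1.0 + math.exp(-2.0 * q))


def source_mass(entry) -> Tuple[Dict[str, float], Optional[int]]:
    """Probability mass function of a source entry.

    Returns (mass, n_guesses); n_guesses is None for corpus distributions.
    Corpus tail mass is treated as non-matching and simply omitted.
    """
    if isinstance(entry, ClozeResponseSet):
        return response_shares(entry), entry.n_guesses
    if isinstance(entry, ProbDistribution):
        return dict(entry.mass), None
    raise PredictabilityError(f"unsupported source entry: {type(entry).__name__}")


def _bound(p: float, n_guesses: Optional[int]) -> float:
    """Clamp a summed mass into (0,1) with source-appropriate smoothing."""
    if n_guesses is not None:
        lo, hi = smooth_zero(n_guesses), cap_one(n_guesses)
    else:
        lo, hi = CORPUS_FLOOR, 1.0 - CORPUS_FLOOR
    return min(max(p, lo), hi)


def class_probability(entry, target_analyses, lexicon: MorphLexicon) -> float:
    """Total source mass on candidates sharing a word class with the target."""
    target = list(target_analyses)
    if not target:
        raise PredictabilityError("target has no analyses")
    mass, n = source_mass(entry)
    total = sum(p for form, p in mass.items()
                if class_match(analyze(form, lexicon), target))
    return _bound(total, n)


def feature_probability(entry, target_analyses, feature: str,
                        lexicon: MorphLexicon,
                        renormalize_within_class: bool = False) -> float:
    """Total source mass on candidates feature-matching the target.

    By default the denominator is the full candidate mass; with
    ``renormalize_within_class`` the matching mass is divided by the mass of
    candidates class-matching the target.
    """
    target = list(target_analyses)
    if not target:
        raise PredictabilityError("target has no analyses")
    if not any(a.feature(feature) is not None for a in target):
        raise PredictabilityError(f"target does not define feature {feature!r}")
    mass, n = source_mass(entry)
    matched = 0.0
    in_class = 0.0
    for form, p in mass.items():
        cand = analyze(form, lexicon)
        if class_match(cand, target):
            in_class += p
            if feature_match(cand, target, feature):
                matched += p
    if renormalize_within_class:
        if in_class <= 0.0:
            return _bound(0.0, n)
        return _bound(matched / in_class, n)
    return _bound(matched, n)


def target_features(analyses) -> List[str]:
    """Features defined by at least one analysis of the target."""
    feats: set = set()
    for a in analyses:
        feats.update(k for k, _ in a.features)
    return sorted(feats)


@dataclass(frozen=True)
class WordPredictability:
    word_id: Tuple[object, int]
    source: str  # "cloze" | "corpus"
    p_lexical: float
    q_lexical: float
    p_class: float
    p_feature: Mapping[str, float]
    smoothed: bool = False


def word_predictability(entry, target_form: str, lexicon: MorphLexicon,
                        word_id=None, source: str = "") -> WordPredictability:
    """All predictability measures of one target word from one source."""
    from .cloze import lexical_probability, normalize_response

    target_analyses = analyze(target_form, lexicon)
    mass, n = source_mass(entry)
    if n is not None:
        rec = lexical_probability(entry, target_form)
        p_lex, smoothed = rec.p_lexical, rec.smoothed
    else:
        p_lex = _bound(mass.get(normalize_response(target_form), 0.0), None)
        smoothed = False
    p_class = class_probability(entry, target_analyses, lexicon)
    p_feat = {f: feature_probability(entry, target_analyses, f, lexicon)
              for f in target_features(target_analyses)}
    return WordPredictability(word_id, source, p_lex, logit_transform(p_lex),
                              p_class, p_feat, smoothed)


_FEATURES = ("gender", "number", "case", "tense", "person")


def predictability_table(stimuli: pd.DataFrame,
                         cloze_sets: Mapping,
                         dist_table,
                         lexicon: MorphLexicon) -> pd.DataFrame:
    """Per-word predictability from both sources, one row per stimulus word.

    ``stimuli`` needs sentence_id, position, form, is_first, is_last.
    Sentence-initial words get corpus measures only (no cloze record exists
    for them); their cloze columns are NaN.
    """
    rows = []
    for _, w in stimuli.iterrows():
        key = (w["sentence_id"], int(w["position"]))
        analyses = analyze(w["form"], lexicon)
        classes = sorted({a.word_class for a in analyses})
        row = {
            "sentence_id": w["sentence_id"], "position": int(w["position"]),
            "form": w["form"], "is_first": int(w["is_first"]),
            "is_last": int(w["is_last"]),
            "target_class": classes[0], "ambiguous_class": len(classes) > 1,
        }
        sources = []
        if not int(w["is_first"]) and key in cloze_sets:
            sources.append(("cloze", cloze_sets[key]))
        if dist_table is not None and key in dist_table:
            sources.append(("corpus", dist_table.get(*key)))
        for name, entry in sources:
            wp = word_predictability(entry, w["form"], lexicon, key, name)
            row[f"p_lex_{name}"] = wp.p_lexical
            row[f"q_lex_{name}"] = wp.q_lexical
            row[f"p_class_{name}"] = wp.p_class
            row[f"q_class_{name}"] = logit_transform(wp.p_class)
            if name == "cloze":
                row["smoothed"] = wp.smoothed
                row["n_guesses"] = cloze_sets[key].n_guesses
            for feat in _FEATURES:
                if feat in wp.p_feature:
                    row[f"p_{feat}_{name}"] = wp.p_feature[feat]
                    row[f"q_{feat}_{name}"] = logit_transform(wp.p_feature[feat])
        rows.append(row)
    return pd.DataFrame(rows)


def correlate(pairs: Sequence[Tuple[float, float]], method: str = "pearson",
              zero_policy: str = "smooth",
              smoothed: Optional[Sequence[bool]] = None) -> float:
    """Correlation between two probability sources.

    ``pairs`` are (cloze, corpus) values — logits for Pearson, raw
    probabilities for Spearman.  ``zero_policy='drop'`` removes pairs whose
    cloze value was smoothed from zero; ``'smooth'`` keeps them.
    """
    if method not in ("pearson", "spearman"):
        raise PredictabilityError(f"unknown method {method!r}")
    if zero_policy not in ("drop", "smooth"):
        raise PredictabilityError(f"unknown zero_policy {zero_policy!r}")
    arr = np.asarray(pairs, dtype=float)
    if zero_policy == "drop" and smoothed is not None:
        arr = arr[~np.asarray(smoothed, dtype=bool)]
    if len(arr) < 3:
        raise PredictabilityError("need at least 3 pairs after policy application")
    if method == "pearson":
        return float(stats.pearsonr(arr[:, 0], arr[:, 1])[0])
    return float(stats.spearmanr(arr[:, 0], arr[:, 1])[0])


def cumulative_correlation_curve(p_cloze: Sequence[float],
                                 q_cloze: Sequence[float],
                                 q_corpus: Sequence[float],
                                 smoothed: Sequence[bool],
                                 thresholds: Sequence[float]) -> List[Tuple[float, float]]:
    """Pearson correlation over words with cloze probability below each threshold.

    Smoothed-zero records are excluded throughout; grid points with fewer
    than 3 remaining pairs are omitted.
    """
    p = np.asarray(p_cloze, float)
    qx = np.asarray(q_cloze, float)
    qy = np.asarray(q_corpus, float)
    sm = np.asarray(smoothed, bool)
    out: List[Tuple[float, float]] = []
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise PredictabilityError("thresholds must lie in (0,1]")
        sel = (~sm) & (p < t)
        if sel.sum() < 3:
            continue
        out.append((float(t), float(stats.pearsonr(qx[sel], qy[sel])[0])))
    return out


def _group_stats(sub: pd.DataFrame, col_x: str, col_y: str) -> dict:
    n = len(sub)
    stats_row = {"n_words": n}
    for col, label in ((col_x, "cloze"), (col_y, "corpus")):
        vals = sub[col].astype(float)
        stats_row[f"mean_{label}"] = float(vals.mean())
        stats_row[f"se_{label}"] = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    if n >= 3 and sub[col_x].nunique() > 1 and sub[col_y].nunique() > 1:
        stats_row["pearson"] = float(stats.pearsonr(sub[col_x], sub[col_y])[0])
    else:
        stats_row["pearson"] = float("nan")
    return stats_row


def summarize_by_class(table: pd.DataFrame,
                       col_cloze: str = "p_class_cloze",
                       col_corpus: str = "p_class_corpus") -> pd.DataFrame:
    """Per-class means, standard errors and cloze/corpus Pearson correlations.

    Includes content-word, function-word and all-word rollups, mirroring the
    usual word-class summary layout.
    """
    sub = table.dropna(subset=[col_cloze, col_corpus])
    rows = []
    order = list(CONTENT_CLASSES) + list(FUNCTION_CLASSES)
    for wc in order:
        grp = sub[sub["target_class"] == wc]
        if len(grp) == 0:
            continue
        rows.append({"word_class": wc, **_group_stats(grp, col_cloze, col_corpus)})
    content = sub[sub["target_class"].isin(CONTENT_CLASSES)]
    function = sub[sub["target_class"].isin(FUNCTION_CLASSES)]
    if len(content):
        rows.append({"word_class": "all_content", **_group_stats(content, col_cloze, col_corpus)})
    if len(function):
        rows.append({"word_class": "all_function", **_group_stats(function, col_cloze, col_corpus)})
    if len(sub):
        rows.append({"word_class": "all_words", **_group_stats(sub, col_cloze, col_corpus)})
    return pd.DataFrame(rows)
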