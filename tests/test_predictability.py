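import math

import numpy as np
import pandas as pd
import pytest

from predread.cloze import ClozeResponseSet, cap_one, smooth_zero
from predread.language_model import ProbDistribution
from predread.morphology import FEATURE_VALUES, MorphAnalysis, MorphLexicon, analyze
from predread.predictability import (
    CORPUS_FLOOR,
    PredictabilityError,
    class_probability,
    correlate,
    cumulative_correlation_curve,
    feature_probability,
    inverse_logit,
    logit_transform,
    summarize_by_class,
    word_predictability,
)


def _a(word_class, **feats):
    return MorphAnalysis(word_class, frozenset({(k, str(v)) for k, v in feats.items()}))


class TestLogitTransform:
    def test_half_maps_to_zero(self):
        assert logit_transform(0.5) == 0.0

    @pytest.mark.parametrize("p", [0.01, 0.2, 0.49, 0.8, 0.999])
    def test_antisymmetry(self, p):
        assert logit_transform(p) == pytest.approx(-logit_transform(1 - p), abs=1e-12)

    def test_printed_formula_value(self):
        assert logit_transform(0.1) == pytest.approx(0.5 * math.log(1 / 9), abs=1e-15)

    def test_round_trip_on_grid(self):
        grid = np.linspace(0.001, 0.999, 1000)
        for p in grid:
            assert inverse_logit(logit_transform(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(PredictabilityError):
            logit_transform(p)


@pytest.fixture
def cloze_entry():
    # driver:2, car:1, quickly:1 → shares 0.5 / 0.25 / 0.25
    return ClozeResponseSet(("s1", 2), ("driver", "driver", "car", "quickly"))


class TestClassProbability:
    def test_noun_mass_summation(self, toy_lexicon, cloze_entry):
        target = analyze("driver", toy_lexicon)
        assert class_probability(cloze_entry, target, toy_lexicon) == pytest.approx(0.75)

    def test_all_in_class_is_capped(self, toy_lexicon):
        entry = ClozeResponseSet(("s1", 2), ("driver",) * 10)
        target = analyze("car", toy_lexicon)
        assert class_probability(entry, target, toy_lexicon) == pytest.approx(cap_one(10))

    def test_zero_mass_smoothed_cloze(self, toy_lexicon, cloze_entry):
        target = analyze("drove", toy_lexicon)  # verb target, no verb guesses
        assert class_probability(cloze_entry, target, toy_lexicon) \
            == pytest.approx(smooth_zero(4))

    def test_zero_mass_floored_corpus(self, toy_lexicon):
        dist = ProbDistribution(None, {"quickly": 1.0})
        target = analyze("driver", toy_lexicon)
        assert class_probability(dist, target, toy_lexicon) == pytest.approx(CORPUS_FLOOR)

    def test_class_probability_dominates_lexical(self, toy_lexicon, cloze_entry):
        wp = word_predictability(cloze_entry, "driver", toy_lexicon)
        assert wp.p_class >= wp.p_lexical


class TestFeatureProbability:
    def test_partial_case_mass(self, toy_lexicon):
        # noun mass: driver (nom) 0.5, car (acc) 0.25; adverb 0.25.
        entry = ClozeResponseSet(("s1", 2), ("driver", "driver", "car", "quickly"))
        target = analyze("car", toy_lexicon)  # accusative noun
        assert feature_probability(entry, target, "case", toy_lexicon) \
            == pytest.approx(0.25)

    def test_ambiguous_target_counts_either_reading(self, toy_lexicon):
        entry = ClozeResponseSet(("s1", 2), ("driver", "car"))  # nom + acc nouns
        target = analyze("mouth", toy_lexicon)  # nom-or-acc
        assert feature_probability(entry, target, "case", toy_lexicon) \
            == pytest.approx(cap_one(2))

    def test_renormalization_within_class(self, toy_lexicon):
        entry = ClozeResponseSet(("s1", 2), ("driver", "car", "quickly", "quickly"))
        target = analyze("car", toy_lexicon)
        plain = feature_probability(entry, target, "case", toy_lexicon)
        renorm = feature_probability(entry, target, "case", toy_lexicon,
                                     renormalize_within_class=True)
        assert plain == pytest.approx(0.25)
        assert renorm == pytest.approx(0.5)

    def test_undefined_feature_rejected(self, toy_lexicon):
        entry = ClozeResponseSet(("s1", 2), ("driver",))
        with pytest.raises(PredictabilityError):
            feature_probability(entry, analyze("quickly", toy_lexicon),
                                "case", toy_lexicon)


def _random_tagged_setup(rng):
    """Random small lexicon + integer response counts for symmetry checks."""
    lex = MorphLexicon()
    forms = [f"w{i}" for i in range(rng.integers(4, 9))]
    for form in forms:
        wc = rng.choice(["noun", "verb_finite", "adjective", "adverb"])
        if wc == "noun":
            a = _a("noun", gender=rng.choice(FEATURE_VALUES["gender"]),
                   number=rng.choice(FEATURE_VALUES["number"]),
                   case=rng.choice(FEATURE_VALUES["case"]))
        elif wc == "verb_finite":
            a = _a("verb_finite", tense="past",
                   number=rng.choice(FEATURE_VALUES["number"]),
                   gender=rng.choice(FEATURE_VALUES["gender"]))
        else:
            a = _a(wc)
        lex.add(form, [a])
    counts = {f: int(rng.integers(0, 6)) for f in forms}
    if sum(counts.values()) == 0:
        counts[forms[0]] = 1
    return lex, forms, counts


def test_cloze_and_corpus_sources_agree_on_identical_mass():
    """A cloze multiset and a corpus distribution encoding the same mass
    function yield identical class and feature probabilities."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        lex, forms, counts = _random_tagged_setup(rng)
        n = sum(counts.values())
        responses = tuple(f for f, c in counts.items() for _ in range(c))
        cloze_set = ClozeResponseSet(("s", 2), responses)
        dist = ProbDistribution(None, {f: c / n for f, c in counts.items() if c})
        target_form = forms[int(rng.integers(len(forms)))]
        target = analyze(target_form, lex)
        pc_cloze = class_probability(cloze_set, target, lex)
        pc_corpus = class_probability(dist, target, lex)
        # Identical except for the source-specific smoothing bounds.
        raw = sum(c / n for f, c in counts.items()
                  if analyze(f, lex) and list(analyze(f, lex))[0].word_class
                  == list(target)[0].word_class)
        if smooth_zero(n) <= raw <= cap_one(n):
            assert pc_cloze == pytest.approx(pc_corpus, abs=1e-12)


def test_class_mass_conservation(toy_lexicon):
    """With an unambiguous lexicon, class masses partition the total mass;
    permissive ambiguity can only increase the sum."""
    entry = ClozeResponseSet(("s1", 2), ("driver", "car", "quickly", "drove"))
    classes = {"noun": "driver", "adverb": "quickly", "verb_finite": "drove"}
    total = 0.0
    for wc, probe in classes.items():
        mass = sum(1 / 4 for f in ("driver", "car", "quickly", "drove")
                   if list(analyze(f, toy_lexicon))[0].word_class == wc)
        total += mass
    assert total == pytest.approx(1.0, abs=1e-9)
    # Ambiguous candidate: double membership can push summed class mass > 1.
    lex = MorphLexicon()
    lex.add("x", [_a("noun", case="nom"), _a("adjective")])
    entry2 = ClozeResponseSet(("s1", 2), ("x",))
    p_noun = class_probability(entry2, [_a("noun", case="nom")], lex)
    p_adj = class_probability(entry2, [_a("adjective")], lex)
    assert p_noun + p_adj >= 1.0


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        pairs = [(x, 2 * x + 1) for x in np.linspace(-2, 2, 10)]
        assert correlate(pairs, "pearson") == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.3, size=20)
        base = correlate(list(zip(x, y)), "spearman")
        warped = correlate(list(zip(np.exp(x), y)), "spearman")
        assert base == pytest.approx(warped, abs=1e-12)

    def test_matches_textbook_formula_on_fixed_pairs(self):
        x = np.array([0.1, 0.4, 0.2, 0.8, 0.5, 0.9, 0.3, 0.6, 0.7, 0.05])
        y = np.array([0.2, 0.5, 0.1, 0.7, 0.4, 0.95, 0.35, 0.5, 0.8, 0.15])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert correlate(list(zip(x, y)), "pearson") == pytest.approx(num / den, abs=1e-12)

    def test_drop_policy_removes_smoothed_pairs(self):
        pairs = [(1, 1), (2, 2), (3, 3), (4, -10)]
        smoothed = [False, False, False, True]
        assert correlate(pairs, "pearson", "drop", smoothed) == pytest.approx(1.0)

    def test_insufficient_pairs(self):
        with pytest.raises(PredictabilityError):
            correlate([(1, 1), (2, 2)], "pearson")


class TestCumulativeCurve:
    def test_full_threshold_equals_drop_correlation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.95, 30)
        qx = rng.normal(size=30)
        qy = qx + rng.normal(scale=0.5, size=30)
        sm = np.zeros(30, bool)
        curve = cumulative_correlation_curve(p, qx, qy, sm, [1.0])
        expected = correlate(list(zip(qx, qy)), "pearson", "drop", sm)
        assert curve == [(1.0, pytest.approx(expected))]

    def test_threshold_below_minimum_omitted(self):
        curve = cumulative_correlation_curve([0.5, 0.6, 0.7], [1, 2, 3],
                                             [1, 2, 3], [False] * 3, [0.01])
        assert curve == []

    def test_decreasing_curve_when_low_probability_noise_is_smaller(self):
        # Construct logits tightly coupled at low cloze p, noisy at high p.
        rng = np.random.default_rng(2)
        p = np.concatenate([np.full(40, 0.05), np.full(40, 0.8)])
        qx = rng.normal(size=80)
        noise = np.where(p < 0.5, 0.05, 2.0)
        qy = qx + rng.normal(size=80) * noise
        curve = dict(cumulative_correlation_curve(p, qx, qy, np.zeros(80, bool),
                                                  [0.5, 1.0]))
        assert curve[0.5] > curve[1.0]


def test_summarize_by_class_hand_means():
    table = pd.DataFrame({
        "target_class": ["noun", "noun", "noun", "adverb", "preposition", "preposition"],
        "p_class_cloze": [0.6, 0.8, 0.7, 0.4, 0.5, 0.5],
        "p_class_corpus": [0.5, 0.9, 0.7, 0.3, 0.6, 0.6],
    })
    out = summarize_by_class(table).set_index("word_class")
    assert out.at["noun", "mean_cloze"] == pytest.approx(0.7)
    assert out.at["noun", "n_words"] == 3
    assert out.at["adverb", "se_cloze"] == 0.0          # single word
    assert out.at["preposition", "se_cloze"] == 0.0     # two equal values
    assert out.at["all_content", "n_words"] == 4
    assert out.at["all_function", "n_words"] == 2
    assert out.at["all_words", "mean_corpus"] == pytest.approx(np.mean([0.5, 0.9, 0.7, 0.3, 0.6, 0.6]))
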