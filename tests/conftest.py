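import pandas as pd
import pytest

from predread.morphology import MorphAnalysis, MorphLexicon
from predread.reading_measures import build_table, fixations_from_frame, trial_measures_frame
from predread.synthetic_data import SimConfig, make_bundle


def _a(word_class, **feats):
    return MorphAnalysis(word_class, frozenset({(k, str(v)) for k, v in feats.items()}))


@pytest.fixture(scope="session")
def toy_lexicon():
    """Hand-built lexicon with unambiguous and ambiguous entries."""
    lex = MorphLexicon()
    lex.add("driver", [_a("noun", gender="m", number="sg", case="nom")])
    lex.add("car", [_a("noun", gender="f", number="sg", case="acc")])
    lex.add("pedestrian", [_a("noun", gender="m", number="sg", case="nom")])
    lex.add("quickly", [_a("adverb")])
    lex.add("drove", [_a("verb_finite", tense="past", number="sg", gender="m")])
    lex.add("drives", [_a("verb_finite", tense="present", number="sg", person="3")])
    # "rot"-style case ambiguity: nominative or accusative singular.
    lex.add("mouth", [_a("noun", gender="m", number="sg", case="nom"),
                      _a("noun", gender="m", number="sg", case="acc")])
    return lex


def table_from_bundle(bundle):
    meas = trial_measures_frame(fixations_from_frame(bundle.fixations))
    return build_table(meas, bundle.pred_table, bundle.frequencies, bundle.stimuli)


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap synthetic study reused by read-only tests."""
    return make_bundle(SimConfig(n_sentences=20, n_participants=6), seed=11)


@pytest.fixture(scope="session")
def small_table(small_bundle):
    return table_from_bundle(small_bundle)
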