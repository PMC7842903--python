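import filecmp
import math

import numpy as np
import pandas as pd
import pytest

from predread.morphology import analyze
from predread.reading_measures import (
    compute_measures,
    fixations_from_frame,
    trial_measures_frame,
)
from predread.synthetic_data import (
    SimConfig,
    distort_distribution,
    make_bundle,
    make_lexicon,
    make_frequencies,
    make_stimuli_and_truth,
    sample_cloze,
    simulate_reading,
    write_bundle,
)


class TestLexicon:
    def test_zero_ambiguity_gives_single_analyses(self):
        lex = make_lexicon(n_forms=120, ambiguity_rate=0.0, seed=1)
        assert all(len(lex.lookup(f)) == 1 for f in lex.forms)

    def test_pure_class_mix(self):
        lex = make_lexicon(n_forms=60, ambiguity_rate=0.0,
                           class_mix={"noun": 1.0}, seed=2)
        assert {a.word_class for f in lex.forms for a in lex.lookup(f)} == {"noun"}

    def test_regeneration_is_identical(self, tmp_path):
        from predread.morphology import write_lexicon
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_lexicon(make_lexicon(n_forms=150, seed=7), a)
        write_lexicon(make_lexicon(n_forms=150, seed=7), b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_class_mix_rejected(self):
        with pytest.raises(ValueError):
            make_lexicon(class_mix={})

    def test_class_mix_shares_are_respected(self):
        lex = make_lexicon(n_forms=2000, ambiguity_rate=0.0, seed=3)
        nouns = sum(1 for f in lex.forms
                    if list(lex.lookup(f))[0].word_class == "noun")
        assert nouns / 2000 == pytest.approx(0.37, abs=0.05)


class TestStimuli:
    def test_lengths_and_mean(self):
        lex = make_lexicon(n_forms=150, seed=4)
        stim, _ = make_stimuli_and_truth(144, (5, 13), lex, seed=4)
        lengths = stim.groupby("sentence_id")["position"].max()
        assert lengths.between(5, 13).all()
        assert lengths.mean() == pytest.approx(9.0, abs=0.6)

    def test_truth_distributions_are_normalized_and_cover_stimuli(self):
        lex = make_lexicon(n_forms=100, seed=5)
        stim, truth = make_stimuli_and_truth(10, (5, 13), lex, seed=5)
        assert sum(truth.initial.values()) == pytest.approx(1.0, abs=1e-9)
        for sid, sent in stim.groupby("sentence_id"):
            prev = None
            for _, w in sent.sort_values("position").iterrows():
                dist = truth.distribution(prev)
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
                assert dist.get(w["form"], 0) > 0
                prev = w["form"]

    def test_deterministic_successor_chain_gives_point_masses(self):
        lex = make_lexicon(n_forms=40, seed=6)
        _, truth = make_stimuli_and_truth(5, (5, 8), lex, seed=6, n_successors=1)
        for dist in truth.transitions.values():
            assert len(dist) == 1
            assert next(iter(dist.values())) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_seed_reproduces_stimuli(self):
        lex = make_lexicon(n_forms=80, seed=8)
        a, _ = make_stimuli_and_truth(12, (5, 13), lex, seed=8)
        b, _ = make_stimuli_and_truth(12, (5, 13), lex, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestCloze:
    def test_guess_counts_within_stated_range(self):
        lex = make_lexicon(n_forms=80, seed=9)
        stim, truth = make_stimuli_and_truth(12, (5, 13), lex, seed=9)
        resp = sample_cloze(truth, stim, seed=9)
        counts = resp.groupby(["sentence_id", "position"]).size()
        assert counts.between(20, 151).all()
        assert counts.mean() == pytest.approx(47, abs=5)

    def test_unbiased_guesses_converge_to_truth(self):
        """Pooling guesses across seeds, the empirical shares approach the
        true conditional distribution (total variation < 0.05)."""
        lex = make_lexicon(n_forms=60, seed=10)
        stim, truth = make_stimuli_and_truth(3, (5, 8), lex, seed=10)
        word = stim[stim["position"] == 2].iloc[0]
        prev = stim[(stim["sentence_id"] == word["sentence_id"]) &
                    (stim["position"] == 1)]["form"].iloc[0]
        true_dist = truth.distribution(prev)
        pooled = {}
        n = 0
        for seed in range(40):
            resp = sample_cloze(truth, stim, seed=seed, bias=0.0)
            sel = resp[(resp["sentence_id"] == word["sentence_id"]) &
                       (resp["position"] == 2)]
            for r in sel["response"]:
                pooled[r] = pooled.get(r, 0) + 1
            n += len(sel)
        assert n > 1500
        tv = 0.5 * sum(abs(pooled.get(f, 0) / n - p) for f, p in true_dist.items())
        assert tv < 0.05

    def test_length_bias_shortens_guesses(self):
        lex = make_lexicon(n_forms=80, seed=11)
        stim, truth = make_stimuli_and_truth(10, (5, 10), lex, seed=11)
        shorter = 0
        for seed in range(6):
            flat = sample_cloze(truth, stim, seed=seed, bias=0.0)
            biased = sample_cloze(truth, stim, seed=seed, bias=0.5)
            shorter += (biased["response"].str.len().mean()
                        < flat["response"].str.len().mean())
        assert shorter == 6

    def test_point_mass_truth_gives_identical_guesses(self):
        lex = make_lexicon(n_forms=40, seed=12)
        stim, truth = make_stimuli_and_truth(4, (5, 8), lex, seed=12,
                                             n_successors=1)
        resp = sample_cloze(truth, stim, seed=12)
        for (_sid, _pos), grp in resp.groupby(["sentence_id", "position"]):
            assert grp["response"].nunique() == 1


class TestDistortion:
    def test_high_concentration_recovers_truth(self):
        lex = make_lexicon(n_forms=60, seed=13)
        stim, truth = make_stimuli_and_truth(6, (5, 8), lex, seed=13)
        table = distort_distribution(truth, stim, concentration=1e6, seed=13)
        worst = 0.0
        for (sid, pos), dist in table.items():
            stim_row = stim[(stim["sentence_id"] == sid) & (stim["position"] == pos)]
            prev = None if pos == 1 else stim[
                (stim["sentence_id"] == sid) & (stim["position"] == pos - 1)
            ]["form"].iloc[0]
            true_dist = truth.distribution(prev)
            for f, p in true_dist.items():
                worst = max(worst, abs(dist.mass.get(f, 0.0) - p))
        assert worst < 1e-2

    def test_distributions_stay_normalized(self):
        lex = make_lexicon(n_forms=60, seed=14)
        stim, truth = make_stimuli_and_truth(6, (5, 8), lex, seed=14)
        table = distort_distribution(truth, stim, concentration=3.0, seed=14)
        for _key, dist in table.items():
            assert dist.total() == pytest.approx(1.0, abs=1e-8)
            assert all(p > 0 for p in dist.mass.values())

    def test_fixed_seed_identical_files(self, tmp_path):
        lex = make_lexicon(n_forms=40, seed=15)
        stim, truth = make_stimuli_and_truth(4, (5, 8), lex, seed=15)
        a, b = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        distort_distribution(truth, stim, 50.0, seed=15).to_jsonl(a)
        distort_distribution(truth, stim, 50.0, seed=15).to_jsonl(b)
        assert a.read_bytes() == b.read_bytes()

    def test_nonpositive_concentration_rejected(self):
        lex = make_lexicon(n_forms=20, seed=16)
        stim, truth = make_stimuli_and_truth(2, (5, 6), lex, seed=16)
        with pytest.raises(ValueError):
            distort_distribution(truth, stim, 0.0, seed=16)


class TestReadingSimulation:
    def test_degenerate_model_pins_gaze_durations_to_intercept(self):
        cfg = SimConfig(n_sentences=4, n_participants=3, beta={},
                        sd_participant=0.0, sd_sentence=0.0, sd_word=0.0,
                        sd_residual=0.0, skip_on=None)
        lex = make_lexicon(cfg.n_forms, cfg.ambiguity_rate, seed=17)
        stim, truth = make_stimuli_and_truth(cfg.n_sentences, cfg.length_range,
                                             lex, seed=17)
        pred = pd.DataFrame({"sentence_id": stim["sentence_id"],
                             "position": stim["position"]})
        fx = simulate_reading(stim, pred, cfg, seed=17)
        meas = trial_measures_frame(fixations_from_frame(fx))
        assert np.allclose(meas["GD"], math.exp(cfg.intercept), atol=0.01)

    def test_predictability_speeds_reading(self):
        """Mean log gaze duration decreases across predictability terciles."""
        ok = 0
        for seed in range(3):
            cfg = SimConfig(n_sentences=30, n_participants=10)
            b = make_bundle(cfg, seed=20 + seed)
            meas = trial_measures_frame(fixations_from_frame(b.fixations))
            merged = meas.merge(b.pred_table, on=["sentence_id", "position"])
            merged = merged.dropna(subset=["q_lex_cloze", "GD"])
            terciles = pd.qcut(merged["q_lex_cloze"], 3, labels=False)
            means = np.log(merged["GD"]).groupby(terciles).mean()
            ok += means.iloc[0] > means.iloc[1] > means.iloc[2]
        assert ok >= 2

    def test_round_trip_measure_ordering(self, small_bundle):
        meas = trial_measures_frame(fixations_from_frame(small_bundle.fixations))
        assert (meas["FFD"] <= meas["GD"] + 1e-9).all()
        assert (meas["GD"] <= meas["TT"] + 1e-9).all()

    def test_saccade_amplitudes_are_consistent(self, small_bundle):
        fx = small_bundle.fixations
        one = fx[(fx["participant_id"] == fx["participant_id"].iloc[0])
                 & (fx["sentence_id"] == fx["sentence_id"].iloc[0])]
        assert one.iloc[0]["saccade_amp_char"] == 0.0
        assert (one["saccade_amp_char"] >= 0).all()


def test_bundle_write_is_byte_deterministic(tmp_path):
    cfg = SimConfig(n_sentences=6, n_participants=3)
    for d in ("a", "b"):
        write_bundle(make_bundle(cfg, seed=21), tmp_path / d)
    cmpres = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
    assert not cmpres.diff_files
    for name in cmpres.common_files:
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_bundle_files_are_mutually_consistent(tmp_path, small_bundle):
    stim_keys = set(zip(small_bundle.stimuli["sentence_id"],
                        small_bundle.stimuli["position"]))
    resp_keys = set(zip(small_bundle.responses["sentence_id"],
                        small_bundle.responses["position"]))
    assert resp_keys <= stim_keys
    non_initial = {(s, p) for s, p in stim_keys if p > 1}
    assert resp_keys == non_initial
    for (sid, pos) in stim_keys:
        assert (sid, pos) in small_bundle.dist_table
    fix_keys = set(zip(small_bundle.fixations["sentence_id"],
                       small_bundle.fixations["word_position"]))
    assert fix_keys <= stim_keys
    forms = set(small_bundle.stimuli["form"])
    assert forms <= set(small_bundle.frequencies)
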