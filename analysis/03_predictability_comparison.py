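"""Compare cloze and corpus-based probabilities on the synthetic study.

Loads the bundle written by 01_simulate_study.py and reports:

* mean lexical probabilities per source and their correlations — Pearson on
  logit values (with and without smoothed zeros) and Spearman on raw
  probabilities;
* the cumulative-correlation curve (Pearson over words with cloze
  probability below each threshold);
* the word-class summary table (means, SEs, per-class correlations, with
  content/function rollups) and the unigram class baseline.

Writes results/correlations.csv, results/cumulative_curve.csv and
results/class_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from predread.language_model import unigram_class_baseline
from predread.morphology import analyze, read_lexicon
from predread.predictability import (
    correlate,
    cumulative_correlation_curve,
    summarize_by_class,
)
from predread.synthetic_data import SimConfig, sample_training_corpus

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1):
    pred = pd.read_csv(ROOT / "study" / "predictability.tsv", sep="\t")
    words = pred[pred["is_first"] == 0].copy()
    print(f"{len(words)} words enter the correlation analyses "
          f"({int(words['smoothed'].sum())} with smoothed zero cloze probability)")
    print(f"mean lexical probability: cloze {words['p_lex_cloze'].mean():.3f}, "
          f"corpus {words['p_lex_corpus'].mean():.3f}")

    pairs = list(zip(words["q_lex_cloze"], words["q_lex_corpus"]))
    raw = list(zip(words["p_lex_cloze"], words["p_lex_corpus"]))
    smoothed = words["smoothed"].astype(bool).tolist()
    rows = [
        {"measure": "pearson_logit_drop_zeros",
         "value": correlate(pairs, "pearson", "drop", smoothed)},
        {"measure": "pearson_logit_with_smoothed_zeros",
         "value": correlate(pairs, "pearson", "smooth")},
        {"measure": "spearman_raw",
         "value": correlate(raw, "spearman", "smooth")},
    ]
    for r in rows:
        print(f"{r['measure']}: {r['value']:.3f}")
    pd.DataFrame(rows).to_csv(ROOT / "correlations.csv", index=False,
                              lineterminator="\n")

    curve = cumulative_correlation_curve(
        words["p_lex_cloze"], words["q_lex_cloze"], words["q_lex_corpus"],
        smoothed, np.round(np.arange(0.1, 1.01, 0.1), 2))
    pd.DataFrame(curve, columns=["threshold", "pearson"]).to_csv(
        ROOT / "cumulative_curve.csv", index=False, lineterminator="\n")
    if curve:
        print(f"cumulative correlation: {curve[0][1]:.3f} at p<{curve[0][0]} "
              f"-> {curve[-1][1]:.3f} at p<{curve[-1][0]}")

    summary = summarize_by_class(words)
    summary.to_csv(ROOT / "class_summary.csv", index=False, lineterminator="\n")
    all_row = summary.set_index("word_class").loc["all_words"]
    print(f"mean word-class probability: cloze {all_row['mean_cloze']:.2f}, "
          f"corpus {all_row['mean_corpus']:.2f}")

    lexicon = read_lexicon(ROOT / "study" / "lexicon.tsv")
    cfg = SimConfig()
    # chain-sampled tagged corpus for the class-frequency baseline
    import json
    truth_raw = json.loads((ROOT / "study" / "truth.json").read_text())
    from predread.synthetic_data import ChainTruth
    truth = ChainTruth(sorted(truth_raw["transitions"]), truth_raw["initial"],
                       truth_raw["transitions"])
    corpus = sample_training_corpus(truth, 400, cfg.length_range, seed)
    tagged = [(tok, analyze(tok, lexicon)) for sent in corpus for tok in sent]
    baseline = unigram_class_baseline(tagged)
    per_word = [baseline.get(wc, 0.0) for wc in words["target_class"]]
    print(f"unigram class baseline: mean probability {np.mean(per_word):.2f} "
          f"(vs {all_row['mean_cloze']:.2f} cloze)")


if __name__ == "__main__":
    main()
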