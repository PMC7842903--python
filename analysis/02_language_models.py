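"""Train and evaluate Kneser-Ney n-gram models of increasing order.

Trains interpolated KN models (orders 1, 2, 3 and 5) on the study's
training corpus and scores them on fresh held-out sentences from the same
generative chain: accuracy (argmax hit rate) and perplexity, excluding
sentence-initial tokens.  Because the text really is first-order, the
bigram model captures essentially all structure; higher orders should not
do better — the same model-selection logic used to pick a predictability
model from competing candidates.

Writes results/lm_evaluation.csv.
"""

from pathlib import Path

import pandas as pd

from predread.language_model import evaluate, train_ngram
from predread.synthetic_data import (
    SimConfig,
    make_lexicon,
    make_stimuli_and_truth,
    sample_training_corpus,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1):
    cfg = SimConfig()
    lexicon = make_lexicon(cfg.n_forms, cfg.ambiguity_rate, seed=seed)
    _, truth = make_stimuli_and_truth(cfg.n_sentences, cfg.length_range,
                                      lexicon, seed=seed)
    train = sample_training_corpus(truth, 1500, cfg.length_range, seed)
    test = sample_training_corpus(truth, 300, cfg.length_range, seed + 1)

    rows = []
    for order in (1, 2, 3, 5):
        model = train_ngram(train, order=order, discount=0.75)
        report = evaluate(model, test)
        rows.append({"order": order, "accuracy": report.accuracy,
                     "perplexity": report.perplexity, "n": report.n_evaluated})
        print(f"order {order}: accuracy {report.accuracy:.3f}  "
              f"perplexity {report.perplexity:.1f}  (n={report.n_evaluated})")

    out = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    out.to_csv(ROOT / "lm_evaluation.csv", index=False, lineterminator="\n")
    best = out.loc[out["perplexity"].idxmin()]
    print(f"best model by perplexity: order {int(best['order'])} "
          f"({best['perplexity']:.1f}); unigram baseline "
          f"{out.iloc[0]['perplexity']:.1f}")


if __name__ == "__main__":
    main()
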