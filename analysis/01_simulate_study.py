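"""Generate the synthetic study bundle that the later analyses consume.

Emulates the design of a reading-predictability study: 144 stimulus
sentences of 5-13 words sampled from a known first-order chain, cumulative
cloze guesses (20-151 per word) drawn from the true next-word
distributions, a corpus-model source obtained by perturbing those
distributions, and fixation sequences for 30 participants generated from a
hierarchical lognormal model with a true predictability effect of
-0.05 log-ms per logit unit.

Writes the full bundle (plain text) to results/study/.
"""

import sys
from pathlib import Path

from predread.synthetic_data import SimConfig, make_bundle, write_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 1):
    cfg = SimConfig()
    bundle = make_bundle(cfg, seed=seed)
    write_bundle(bundle, OUT)

    lengths = bundle.stimuli.groupby("sentence_id")["position"].max()
    guesses = bundle.responses.groupby(["sentence_id", "position"]).size()
    print(f"stimuli: {lengths.size} sentences, {len(bundle.stimuli)} words, "
          f"length {lengths.min()}-{lengths.max()} (mean {lengths.mean():.2f})")
    print(f"cloze:   {guesses.min()}-{guesses.max()} guesses per word "
          f"(mean {guesses.mean():.1f}), {len(guesses)} words")
    print(f"corpus:  {len(list(bundle.dist_table.items()))} distributions "
          f"(concentration {cfg.corpus_concentration})")
    print(f"reading: {bundle.fixations['participant_id'].nunique()} participants, "
          f"{len(bundle.fixations)} fixations")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
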