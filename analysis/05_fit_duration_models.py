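"""Fit the hierarchical lognormal fixation-duration models.

For each duration measure (GD and TT here) and each source (cloze,
corpus), fits the baseline and word-class model tiers: log duration on
lengths, frequencies, oculomotor covariates and logit probabilities of the
previous/current/next word, with varying intercepts for participants,
sentences and words.  The generating model had a true current-word effect
of -0.05 log-ms per logit unit on the cloze scale, so the cloze models
should recover a reliably negative current-word coefficient.

Writes one fit summary per model under results/fits/.
"""

import json
from pathlib import Path

import pandas as pd

from predread.rt_models import ModelSpec, fit

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = pd.read_csv(ROOT / "analysis_table.csv")
    table["sentence"] = table["sentence"].astype(str)
    out_dir = ROOT / "fits"
    out_dir.mkdir(parents=True, exist_ok=True)

    for dependent in ("GD", "TT"):
        for source in ("cloze", "corpus"):
            for tier in ("baseline", "word_class"):
                spec = ModelSpec(dependent, tier, source)
                result = fit(table, spec)
                name = f"{dependent}_{tier}_{source}"
                payload = {
                    "spec": {"dependent": dependent, "tier": tier, "source": source},
                    "n_rows": int(result.result.n_rows),
                    "loglik": result.result.loglik,
                    "sigma2": result.result.sigma2,
                    "varcomps": result.result.varcomps,
                    "coefficients": result.summary.to_dict("records"),
                }
                (out_dir / f"{name}.json").write_text(
                    json.dumps(payload, indent=1, default=bool) + "\n")
                cur = result.summary.set_index("term")
                key = f"q_lex_cur_{source}"
                print(f"{name}: n={result.result.n_rows}, "
                      f"beta[{key}] = {cur.at[key, 'estimate']:+.4f} "
                      f"[{cur.at[key, 'lower']:+.4f}, {cur.at[key, 'upper']:+.4f}]"
                      f"{' *' if cur.at[key, 'reliable'] else ''}")


if __name__ == "__main__":
    main()
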