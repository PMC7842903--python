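"""Compare cloze vs corpus models and test residual complementarity.

For GD and TT, compares the cloze and corpus variants of the baseline tier
by 10-fold information criterion (negative differences favour cloze; the
difference is flagged when |delta/SE| >= 2), then regresses each model's
residuals on the other source's probability predictors to ask whether the
two sources explain non-overlapping variance.  In this bundle the
durations were generated from the cloze logits alone, so the comparison
should favour cloze and the corpus predictors should explain little or
nothing beyond it.

Writes results/comparisons.csv and results/residual_analysis.csv.
"""

from pathlib import Path

import pandas as pd

from predread.rt_models import ModelSpec, compare_kfold, fit, residual_complementarity

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1):
    table = pd.read_csv(ROOT / "analysis_table.csv")
    table["sentence"] = table["sentence"].astype(str)

    comparisons = []
    for dependent in ("GD", "TT"):
        cmp = compare_kfold(table, ModelSpec(dependent, "baseline", "cloze"),
                            ModelSpec(dependent, "baseline", "corpus"),
                            k=10, seed=seed)
        comparisons.append({"dependent": dependent, "tier": "baseline",
                            "delta_ic": cmp.delta_ic, "se": cmp.se,
                            "ratio": cmp.ratio, "significant": cmp.significant,
                            "n": cmp.n})
        flag = " (reliable)" if cmp.significant else ""
        print(f"{dependent} cloze-corpus: delta IC {cmp.delta_ic:+.1f} "
              f"(SE {cmp.se:.1f}, ratio {cmp.ratio:+.2f}){flag}")
    pd.DataFrame(comparisons).to_csv(ROOT / "comparisons.csv", index=False,
                                     lineterminator="\n")

    residual_rows = []
    for dependent in ("GD", "TT"):
        for source in ("cloze", "corpus"):
            fitted = fit(table, ModelSpec(dependent, "baseline", source))
            rc = residual_complementarity(table, fitted, seed=seed)
            rc.insert(0, "dependent", dependent)
            rc.insert(1, "residuals_from", source)
            residual_rows.append(rc)
            reliable = rc[(rc["term"] != "intercept") & rc["reliable"]]["term"]
            other = "corpus" if source == "cloze" else "cloze"
            print(f"{dependent} residuals of {source} model ~ {other} predictors: "
                  + (", ".join(reliable) + " reliable" if len(reliable)
                     else "nothing reliable"))
    pd.concat(residual_rows).to_csv(ROOT / "residual_analysis.csv", index=False,
                                    lineterminator="\n")


if __name__ == "__main__":
    main()
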