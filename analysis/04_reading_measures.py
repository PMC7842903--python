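"""Extract fixation-duration measures and build the analysis table.

Derives SFD/FFD/GD/TT per (participant, word) from the simulated fixation
sequences, applies the word-exclusion rules (sentence-initial words out of
the correlation stage; initial and final words out of the eye-tracking
stage), and assembles the per-word analysis table with all duration-model
predictors.

Writes results/measures.tsv and results/analysis_table.csv.
"""

from pathlib import Path

import pandas as pd

from predread.reading_measures import (
    apply_exclusions,
    build_table,
    fixations_from_frame,
    trial_measures_frame,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    study = ROOT / "study"
    fixations = pd.read_csv(study / "fixations.tsv", sep="\t")
    stimuli = pd.read_csv(study / "stimuli.tsv", sep="\t")
    pred = pd.read_csv(study / "predictability.tsv", sep="\t")
    freq_df = pd.read_csv(study / "frequencies.tsv", sep="\t")
    frequencies = dict(zip(freq_df["form"], freq_df["freq_per_million"]))

    meas = trial_measures_frame(fixations_from_frame(fixations))
    meas.to_csv(ROOT / "measures.tsv", sep="\t", index=False, lineterminator="\n")
    single = (meas["n_fixations"] == 1).mean()
    print(f"{len(meas)} fixated (participant, word) records; "
          f"{single:.0%} single-fixation")

    n_all = len(stimuli)
    n_corr = len(apply_exclusions(stimuli, "correlation"))
    n_eye = len(apply_exclusions(stimuli, "eyetracking"))
    print(f"exclusions: {n_all} words -> {n_corr} (correlation stage) "
          f"-> {n_eye} (eye-tracking stage)")

    table = build_table(meas, pred, frequencies, stimuli)
    table.to_csv(ROOT / "analysis_table.csv", index=False, lineterminator="\n")
    print(f"analysis table: {len(table)} rows x {len(table.columns)} columns")
    for dep in ("SFD", "FFD", "GD", "TT"):
        print(f"  {dep}: {table[dep].notna().sum()} usable rows, "
              f"median {table[dep].median():.0f} ms")


if __name__ == "__main__":
    main()
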