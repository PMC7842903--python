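"""Hierarchical lognormal models of fixation durations.

Each model regresses the log of one duration measure (SFD, FFD, GD or TT)
on a tier of predictors, with varying intercepts for participants,
sentences and words.  Tiers are strictly nested: the baseline tier carries
the oculomotor and lexical predictors (lengths, frequencies and logit
lexical probabilities of the previous, current and next word, incoming
saccade amplitude, landing position, base-form flag); the word-class tier
adds word-class probabilities of the current and next word; the feature
tiers add the morphological-feature probabilities appropriate for noun
targets or finite-verb targets (person marking in present/future tense,
gender marking in past tense).

Cloze-based and corpus-based variants of the same tier are compared by a
k-fold information criterion (out-of-fold pointwise predictive densities
on the deviance scale); |ΔIC/SE| ≥ 2 is flagged as a reliable difference.
Residual complementarity asks whether the predictors of one source explain
variance left over by a model fitted with the other source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lmm import LMMResult, _theta_of, fit_crossed_lmm

__all__ = [
    "SHARED_PREDICTORS",
    "TIERS",
    "ModelSpec",
    "FitResult",
    "ComparisonResult",
    "predictor_columns",
    "fit",
    "compare_kfold",
    "residual_complementarity",
]

SHARED_PREDICTORS = (
    "len_prev", "len_cur", "len_next",
    "logfreq_prev", "logfreq_cur", "logfreq_next",
    "sacc_amp", "landing", "base_form",
)

TIERS = ("baseline", "word_class", "noun_features",
         "verb_features_present_future", "verb_features_past")

DEPENDENTS = ("SFD", "FFD", "GD", "TT")

GROUPS = ("participant", "sentence", "word")

#: k-fold comparisons with |delta/se| at or above this are flagged.
SIGNIFICANCE_RATIO = 2.0


class RtModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    dependent: str
    tier: str = "baseline"
    source: str = "cloze"

    def __post_init__(self):
        if self.dependent not in DEPENDENTS:
            raise RtModelError(f"unknown dependent {self.dependent!r}")
        if self.tier not in TIERS:
            raise RtModelError(f"unknown tier {self.tier!r}")
        if self.source not in ("cloze", "corpus"):
            raise RtModelError(f"unknown source {self.source!r}")


def predictor_columns(spec: ModelSpec) -> List[str]:
    """Predictor column names for a spec; tiers are cumulative."""
    src = spec.source
    cols = list(SHARED_PREDICTORS)
    cols += [f"q_lex_prev_{src}", f"q_lex_cur_{src}", f"q_lex_next_{src}"]
    if spec.tier == "baseline":
        return cols
    cols += [f"q_class_cur_{src}", f"q_class_next_{src}"]
    if spec.tier == "word_class":
        return cols
    if spec.tier == "noun_features":
        cols += [f"q_gender_{src}", f"q_case_{src}", f"q_number_{src}"]
    elif spec.tier == "verb_features_present_future":
        cols += [f"q_tense_{src}", f"q_person_{src}", f"q_number_{src}"]
    elif spec.tier == "verb_features_past":
        cols += [f"q_tense_{src}", f"q_gender_{src}", f"q_number_{src}"]
    return cols


def _row_mask(table: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    mask = table[spec.dependent].notna() & (table[spec.dependent] > 0)
    if spec.tier == "noun_features":
        mask &= table["target_class"] == "noun"
    elif spec.tier == "verb_features_present_future":
        mask &= (table["target_class"] == "verb_finite") & \
            table["target_tense"].isin(["present", "future"])
    elif spec.tier == "verb_features_past":
        mask &= (table["target_class"] == "verb_finite") & \
            (table["target_tense"] == "past")
    for col in predictor_columns(spec):
        mask &= table[col].notna()
    return mask


def _design(table: pd.DataFrame, spec: ModelSpec, rows: pd.Index):
    sub = table.loc[rows]
    # Constant predictors (e.g. base_form on a subset where no target is a
    # base form) carry no information and would make the design singular.
    cols = [c for c in predictor_columns(spec)
            if sub[c].to_numpy(float).std() > 0.0]
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in cols])
    names = ["intercept"] + cols
    y = np.log(sub[spec.dependent].to_numpy(float))
    groups = {g: sub[g].to_numpy() for g in GROUPS}
    return y, X, names, groups


@dataclass
class FitResult:
    """One fitted hierarchical lognormal model."""

    spec: ModelSpec
    result: LMMResult
    rows: pd.Index                      # table index of fitted rows
    summary: pd.DataFrame = field(repr=False, default=None)

    @property
    def residuals(self) -> pd.Series:
        """Conditional log-scale residuals, aligned with the fitted rows."""
        return pd.Series(self.result.resid, index=self.rows)

    @property
    def pointwise_logpdf(self) -> pd.Series:
        return pd.Series(self.result.pointwise_logpdf, index=self.rows)


def fit(table: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> FitResult:
    """Fit log(duration) ~ tier predictors + (1|participant) + (1|sentence) + (1|word).

    Estimation is deterministic; ``seed`` is accepted for interface
    stability and ignored.
    """
    if len(table) == 0:
        raise RtModelError("empty analysis table")
    if (table[spec.dependent].dropna() <= 0).any():
        raise RtModelError("durations must be positive")
    rows = table.index[_row_mask(table, spec)]
    if len(rows) == 0:
        raise RtModelError(f"no usable rows for {spec}")
    y, X, names, groups = _design(table, spec, rows)
    res = fit_crossed_lmm(y, X, groups, feature_names=names)
    return FitResult(spec=spec, result=res, rows=rows, summary=res.summary())


@dataclass
class ComparisonResult:
    """k-fold criterion difference between two models (A − B).

    ``delta_ic`` is on the deviance scale (−2·elpd): negative values mean
    model A predicts held-out data better.  ``elpd_diff`` is the raw
    log-density difference (opposite sign convention).
    """

    delta_ic: float
    se: float
    ratio: float
    significant: bool
    elpd_diff: float
    n: int
    k: int


def compare_kfold(table: pd.DataFrame, spec_a: ModelSpec, spec_b: ModelSpec,
                  k: int = 10, seed: int = 0) -> ComparisonResult:
    """Compare two specs on the same dependent by seeded k-fold cross-validation.

    Rows are the intersection of both specs' usable rows, partitioned into k
    random folds at the row level; each model is refitted k times and scored
    on its held-out rows.
    """
    if spec_a.dependent != spec_b.dependent:
        raise RtModelError("specs must share the dependent measure")
    rows = table.index[_row_mask(table, spec_a) & _row_mask(table, spec_b)]
    n = len(rows)
    if k < 2 or k > n:
        raise RtModelError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_of[rng.permutation(n)] = np.arange(n) % k

    # Full-data fits provide warm starts for the fold refits.
    warm = {}
    for j, spec in enumerate((spec_a, spec_b)):
        y_all, X_all, names, g_all = _design(table, spec, rows)
        res = fit_crossed_lmm(y_all, X_all, g_all, feature_names=names)
        warm[j] = _theta_of(res, list(g_all))

    lpd = {0: np.full(n, np.nan), 1: np.full(n, np.nan)}
    for fold in range(k):
        test = fold_of == fold
        train_rows, test_rows = rows[~test], rows[test]
        for j, spec in enumerate((spec_a, spec_b)):
            y_tr, X_tr, names, g_tr = _design(table, spec, train_rows)
            res = fit_crossed_lmm(y_tr, X_tr, g_tr, feature_names=names,
                                  theta0=warm[j])
            y_te, X_te, _, g_te = _design(table, spec, test_rows)
            lpd[j][test] = res.logpdf(y_te, X_te, g_te)

    d_point = -2.0 * (lpd[0] - lpd[1])
    delta = float(d_point.sum())
    se = float(np.sqrt(n * np.var(d_point, ddof=1))) if n > 1 else 0.0
    ratio = delta / se if se > 0 else 0.0
    return ComparisonResult(delta_ic=delta, se=se, ratio=ratio,
                            significant=abs(ratio) >= SIGNIFICANCE_RATIO,
                            elpd_diff=float((lpd[0] - lpd[1]).sum()), n=n, k=k)


def complementary_columns(spec: ModelSpec) -> List[str]:
    """Predictors of the other source, matched to the model's tier."""
    other = "corpus" if spec.source == "cloze" else "cloze"
    mirror = ModelSpec(spec.dependent, spec.tier, other)
    return [c for c in predictor_columns(mirror) if c not in SHARED_PREDICTORS]


def residual_complementarity(table: pd.DataFrame, fitted: FitResult,
                             columns: Optional[Sequence[str]] = None,
                             seed: int = 0) -> pd.DataFrame:
    """Regress a model's residuals on the other source's probability predictors.

    The residual model keeps the same varying intercepts.  Returns a
    coefficient table with 95% intervals and a ``reliable`` flag (interval
    excludes zero); zero-variance predictors are reported as degenerate
    with a zero estimate.
    """
    cols = list(columns) if columns is not None else complementary_columns(fitted.spec)
    sub = table.loc[fitted.rows]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise RtModelError(f"missing complementary columns: {missing}")
    resid = fitted.residuals
    if len(resid) != len(sub):
        raise RtModelError("residuals and rows are misaligned")
    keep = [c for c in cols if sub[c].notna().all()]
    degenerate = [c for c in keep if sub[c].to_numpy(float).std() == 0.0]
    active = [c for c in keep if c not in degenerate]
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in active])
    names = ["intercept"] + active
    groups = {g: sub[g].to_numpy() for g in GROUPS}
    res = fit_crossed_lmm(resid.to_numpy(), X, groups, feature_names=names)
    out = res.summary()
    out["degenerate"] = False
    for c in degenerate + [c for c in cols if c not in keep]:
        out = pd.concat([out, pd.DataFrame([{
            "term": c, "estimate": 0.0, "se": 0.0, "lower": 0.0, "upper": 0.0,
            "reliable": False, "degenerate": True}])], ignore_index=True)
    return out
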