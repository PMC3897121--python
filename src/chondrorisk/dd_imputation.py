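"""Predicting threat status of Data Deficient species and apportioning.

The headline procedure: fit nested predictive logistic GLMs on data-
sufficient species (log10-transformed traits), score DD species, classify
those with p >= threshold as likely threatened, and distribute the
remaining scorable DD species between NT and LC by the observed NT:LC
ratio, conserving totals exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from ._utils import pct, round_half_away
from .risk_models import (
    LogisticDesign,
    ModelComparisonRow,
    ModelFit,
    aicc,
    akaike_weights,
    fit_logistic_glm,
)
from .species import SpeciesTable, derive_features
from .tabulation import CategoryTable

__all__ = [
    "RocResult",
    "ApportionSpec",
    "PredictedCategoryTable",
    "DDPrediction",
    "LOG10_PLUS_ONE",
    "fit_model_sequence",
    "roc_auc",
    "choose_threshold",
    "predict_dd",
    "apportion",
]

# Depth variables can legitimately be 0 m, so they are shifted before the
# log10 transform; lengths and range areas are strictly positive.
LOG10_PLUS_ONE = frozenset({"min_depth_m", "max_depth_m", "depth_range_m", "median_depth_m"})


def _transform(name: str, values: np.ndarray) -> np.ndarray:
    if name in LOG10_PLUS_ONE:
        return np.log10(values + 1.0)
    return np.log10(values)


@dataclasses.dataclass
class RocResult:
    """ROC sweep over a 0..1 threshold grid plus the Mann-Whitney AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    accuracy: np.ndarray
    auc: float
    chosen_threshold: float | None = None


@dataclasses.dataclass
class DDPrediction:
    n_predicted_threatened: int
    probabilities: pd.Series  # indexed by species_id, scorable DD only
    n_scored: int
    n_excluded: int  # DD species lacking the fit's predictors
    threshold: float


@dataclasses.dataclass
class ApportionSpec:
    """Inputs to the NT/LC apportioning of non-threatened scorable DD."""

    n_dd_total: int
    n_dd_scored: int
    n_dd_predicted_threatened: int
    nt_count_observed: int
    lc_count_observed: int
    ratio: float | None = None  # observed NT:LC; derived when omitted
    mode: str = "share"  # "share" reproduces the published counts

    def __post_init__(self):
        if not (
            0 <= self.n_dd_predicted_threatened <= self.n_dd_scored <= self.n_dd_total
        ):
            raise ValueError("need n_pred_thr <= n_scored <= n_dd_total, all >= 0")
        if self.ratio is None:
            if self.lc_count_observed <= 0:
                raise ValueError("cannot derive NT:LC ratio with no LC species")
            self.ratio = self.nt_count_observed / self.lc_count_observed
        if self.ratio <= 0:
            raise ValueError("NT:LC ratio must be positive")
        if self.mode not in ("share", "odds"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class PredictedCategoryTable:
    """Known + estimated counts after imputing DD species' status."""

    grand_total: int
    known: dict[str, int]
    estimated: dict[str, int]

    @property
    def totals(self) -> dict[str, int]:
        return {k: self.known[k] + self.estimated[k] for k in self.known}

    def percents(self) -> dict[str, float]:
        return {k: pct(v, self.grand_total) for k, v in self.totals.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("threatened", "NT", "LC", "DD"):
            total = self.totals[key]
            rows.append(
                {
                    "group": key,
                    "known": self.known[key],
                    "estimated": self.estimated[key],
                    "total": total,
                    "pct_of_total": pct(total, self.grand_total),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# predictive model sequence
# ---------------------------------------------------------------------------

def _predictive_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in predictors:
        cols.append(_transform(c, df[c].to_numpy(dtype=float)))
    return np.column_stack(cols)


def _nagelkerke(ll: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs)


def fit_model_sequence(
    table: SpeciesTable, formulas: Sequence[Sequence[str]]
) -> tuple[list[ModelComparisonRow], list[ModelFit]]:
    """Fit nested predictive GLMs of increasing complexity.

    Every model is fitted on the same complete-case subset (rows with all
    predictors appearing in any formula), with log10-transformed traits and
    no standardisation.  Returns comparison rows (AICc, delta, weight,
    in-sample AUC, Nagelkerke pseudo-R^2) and the fits themselves.
    """
    t = derive_features(table)
    df = t.df
    all_predictors: list[str] = []
    for f in formulas:
        for c in f:
            if c not in df.columns:
                raise KeyError(f"formula references missing column {c!r}")
            if c not in all_predictors:
                all_predictors.append(c)
    keep = df["threatened"].notna()
    for c in all_predictors:
        keep &= df[c].notna()
    sub = df.loc[keep]
    y = sub["threatened"].to_numpy(dtype=float)
    n = len(sub)

    # intercept-only reference for pseudo-R^2
    p_bar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    ll_null = float(np.sum(y * np.log(p_bar) + (1 - y) * np.log(1 - p_bar)))

    fits: list[ModelFit] = []
    entries = []
    aucs: list[float | None] = []
    r2s: list[float | None] = []
    for f in formulas:
        X = _predictive_matrix(sub, f)
        design = LogisticDesign(
            y=y, X=X, columns=["(Intercept)"] + [f"log10({c})" for c in f]
        )
        fit = fit_logistic_glm(design)
        fit.meta["predictors"] = tuple(f)
        fit.meta["transform"] = "log10"
        fits.append(fit)
        probs = fit.predict_proba(X)
        aucs.append(roc_auc(probs, y).auc if len(np.unique(y)) == 2 else None)
        r2s.append(_nagelkerke(fit.loglik, ll_null, n))
        label = "~ " + (" + ".join(f) if f else "1")
        entries.append((label, fit.loglik, fit.k, tuple(f)))

    aiccs = [aicc(ll, k, n) for _, ll, k, _ in entries]
    weights = akaike_weights(aiccs)
    best = min(aiccs)
    rows = [
        ModelComparisonRow(
            label=label,
            k=k,
            loglik=ll,
            aicc=aiccs[i],
            delta_aicc=aiccs[i] - best,
            weight=float(weights[i]),
            variables=variables,
            auc=aucs[i],
            r2=r2s[i],
        )
        for i, (label, ll, k, variables) in enumerate(entries)
    ]
    return rows, fits


# ---------------------------------------------------------------------------
# ROC / threshold
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, n_thresholds: int = 201) -> RocResult:
    """ROC curves over a 0..1 threshold grid and the tie-aware AUC.

    The AUC is the Mann-Whitney probability that a random positive outranks
    a random negative, with ties counted 1/2 — computed from ranks, so it
    is exact and invariant to monotone transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels, dtype=float)
    if s.shape != yv.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(yv == 1))
    n_neg = int(np.sum(yv == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")

    ranks = rankdata(s)
    auc = (np.sum(ranks[yv == 1]) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    pred = s[None, :] >= thresholds[:, None]
    tp = np.sum(pred & (yv == 1)[None, :], axis=1)
    fp = np.sum(pred & (yv == 0)[None, :], axis=1)
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    accuracy = (tp + tn) / (n_pos + n_neg)
    return RocResult(thresholds, tpr, fpr, accuracy, float(auc))


def choose_threshold(roc: RocResult) -> float:
    """Accuracy-maximising threshold, ties broken toward 0.5."""
    best = np.max(roc.accuracy)
    candidates = roc.thresholds[roc.accuracy >= best - 1e-12]
    chosen = float(min(candidates, key=lambda t: (abs(t - 0.5), t)))
    roc.chosen_threshold = chosen
    return chosen


# ---------------------------------------------------------------------------
# DD prediction & apportioning
# ---------------------------------------------------------------------------

def predict_dd(
    fit: ModelFit, dd_table: SpeciesTable, threshold: float = 0.5
) -> DDPrediction:
    """Score DD species and count those classified threatened (p >= threshold).

    Species lacking any of the fit's predictors are excluded and counted.
    """
    predictors = fit.meta.get("predictors")
    if predictors is None:
        raise ValueError("fit carries no predictor metadata")
    t = derive_features(dd_table)
    df = t.df.loc[t.df["category"] == "DD"]
    ok = pd.Series(True, index=df.index)
    for c in predictors:
        ok &= df[c].notna()
    scored = df.loc[ok]
    n_excluded = int((~ok).sum())
    if len(scored) == 0:
        warnings.warn("no scorable DD species", stacklevel=2)
        return DDPrediction(0, pd.Series(dtype=float), 0, n_excluded, threshold)
    X = _predictive_matrix(scored, predictors)
    probs = expit(X @ fit.coef)
    series = pd.Series(probs, index=scored["species_id"].to_numpy(), name="p_threatened")
    count = int(np.sum(probs >= threshold))
    return DDPrediction(count, series, len(scored), n_excluded, threshold)


def apportion(spec: ApportionSpec, observed: CategoryTable) -> PredictedCategoryTable:
    """Distribute non-threatened scorable DD species between NT and LC.

    mode="share" (default) treats the NT:LC ratio as the NT share of the
    remainder (this reproduces the published counts); mode="odds" reads it
    literally as odds, NT share = r/(1+r).  The rounding remainder goes to
    LC so category counts always sum to the grand total.
    """
    remainder = spec.n_dd_scored - spec.n_dd_predicted_threatened
    share = spec.ratio if spec.mode == "share" else spec.ratio / (1.0 + spec.ratio)
    nt_est = int(round_half_away(share * remainder))
    nt_est = min(nt_est, remainder)
    lc_est = remainder - nt_est
    dd_remaining = spec.n_dd_total - spec.n_dd_scored

    known = {
        "threatened": observed.n_threatened,
        "NT": spec.nt_count_observed,
        "LC": spec.lc_count_observed,
        "DD": dd_remaining,
    }
    estimated = {
        "threatened": spec.n_dd_predicted_threatened,
        "NT": nt_est,
        "LC": lc_est,
        "DD": 0,
    }
    return PredictedCategoryTable(
        grand_total=observed.n_total, known=known, estimated=estimated
    )
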