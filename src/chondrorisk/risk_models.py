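"""Explanatory threat models: logistic GLM/GLMM, AICc comparison, effects.

The mixed model is a binomial GLMM with a logit link and nested taxonomic
random intercepts (order/family/genus).  It is fitted by maximising a
Laplace approximation to the marginal likelihood: for candidate variance
components the joint penalised log-likelihood is maximised over
(coefficients, random effects) by damped Newton iterations, and the
variance components are optimised on the log-SD scale by a derivative-free
outer search.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit

from .species import SpeciesTable, derive_features, standardize

__all__ = [
    "LogisticDesign",
    "ModelFit",
    "ModelComparisonRow",
    "VarianceDecomposition",
    "SeparationError",
    "build_design",
    "fit_logistic_glm",
    "fit_logistic_glmm",
    "aicc",
    "akaike_weights",
    "compare_models",
    "relative_importance",
    "effect_size_pct",
    "r2_glmm",
]

LOGIT_RESIDUAL_VARIANCE = math.pi**2 / 3.0


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclasses.dataclass
class LogisticDesign:
    """Response, fixed-effect matrix, and nested grouping codes."""

    y: np.ndarray  # binary response, shape (n,)
    X: np.ndarray  # fixed effects incl. intercept column, shape (n, p)
    columns: list[str]  # names for X's columns
    groups: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    scaling: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have different lengths")


@dataclasses.dataclass
class ModelFit:
    """A fitted logistic GLM or GLMM."""

    coef: np.ndarray
    se: np.ndarray
    columns: list[str]
    vcomp: dict[str, float]  # per-level random-intercept variances
    loglik: float
    k: int  # number of estimated parameters
    n: int
    converged: bool
    singular: bool = False
    method: str = "glm"
    random_effects: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    meta: dict = dataclasses.field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        z = np.divide(self.coef, self.se, out=np.full_like(self.coef, np.nan),
                      where=self.se > 0)
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": z}, index=self.columns
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Population-level (random effects at zero) fitted probabilities."""
        return expit(np.asarray(X, dtype=float) @ self.coef)


@dataclasses.dataclass
class ModelComparisonRow:
    label: str
    k: int
    loglik: float
    aicc: float
    delta_aicc: float
    weight: float
    variables: tuple[str, ...] = ()
    auc: float | None = None
    r2: float | None = None


@dataclasses.dataclass
class VarianceDecomposition:
    """Nakagawa–Schielzeth style variance partition for a logit GLMM."""

    s2_fixed: float
    s2_random: float
    s2_dist: float = LOGIT_RESIDUAL_VARIANCE

    @property
    def r2_marginal(self) -> float:
        return self.s2_fixed / (self.s2_fixed + self.s2_random + self.s2_dist)

    @property
    def r2_conditional(self) -> float:
        return (self.s2_fixed + self.s2_random) / (
            self.s2_fixed + self.s2_random + self.s2_dist
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    table: SpeciesTable,
    predictors: Sequence[str],
    response: str = "threatened",
    random: Sequence[str] = ("order", "family", "genus"),
    standardize_predictors: bool = True,
    log10_transform: bool = False,
) -> LogisticDesign:
    """Complete-case logistic design from a species table.

    ``response='threatened'`` codes CR/EN/VU as 1 and LC as 0 (NT/DD drop
    out); ``'threatened_nt'`` additionally counts NT as threatened.
    ``log10_transform`` applies log10 before any standardisation (depth
    variables are shifted by 1 m so a 0 m minimum depth stays finite).
    Nested grouping codes are built from the full taxonomy path so that,
    e.g., identically named genera in different families stay distinct.
    Standardisation statistics are computed on the modelled subset only.
    """
    t = derive_features(table)
    df = t.df
    if response == "threatened":
        y = df["threatened"]
    elif response == "threatened_nt":
        y = pd.Series(np.nan, index=df.index)
        y[df["category"].isin(("CR", "EN", "VU", "NT"))] = 1.0
        y[df["category"] == "LC"] = 0.0
    else:
        raise ValueError(f"unknown response coding {response!r}")

    cols = list(predictors)
    needed = df[cols].notna().all(axis=1) & y.notna()
    for level in random:
        needed &= df[level].notna()
    sub = df.loc[needed]

    scaling: dict[str, tuple[float, float]] = {}
    Xcols = [np.ones(len(sub))]
    shift_one = {"min_depth_m", "max_depth_m", "depth_range_m", "median_depth_m"}
    for c in cols:
        v = sub[c].to_numpy(dtype=float)
        if log10_transform:
            v = np.log10(v + 1.0) if c in shift_one else np.log10(v)
        if standardize_predictors:
            mu, sd = float(np.mean(v)), float(np.std(v, ddof=1))
            if sd == 0:
                raise ValueError(f"predictor {c!r} has zero variance")
            scaling[c] = (mu, sd)
            v = (v - mu) / sd
        Xcols.append(v)
    X = np.column_stack(Xcols)

    groups: dict[str, np.ndarray] = {}
    path = None
    for level in random:
        vals = sub[level].astype(str)
        path = vals if path is None else path + "/" + vals
        codes, _ = pd.factorize(path, sort=True)
        groups[level] = codes.astype(np.int64)

    return LogisticDesign(
        y=y.loc[needed].to_numpy(dtype=float),
        X=X,
        columns=["(Intercept)"] + cols,
        groups=groups,
        scaling=scaling,
        ids=sub["species_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_separation(y: np.ndarray, X: np.ndarray, coef: np.ndarray,
                      columns: Sequence[str]) -> None:
    if len(np.unique(y)) < 2:
        raise SeparationError("response is constant (all 0 or all 1)")
    if np.max(np.abs(coef)) > 15.0:
        j = int(np.argmax(np.abs(coef)))
        raise SeparationError(
            f"complete or quasi-complete separation suspected "
            f"(diverging coefficient for {columns[j]!r})"
        )


def fit_logistic_glm(design: LogisticDesign) -> ModelFit:
    """Maximum-likelihood logistic regression by damped Newton iterations."""
    y, X = design.y, design.X
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of coefficients ({n} <= {p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    if len(np.unique(y)) < 2:
        raise SeparationError("response is constant (all 0 or all 1)")

    coef = np.zeros(p)
    ll = _loglik(y, X @ coef)
    converged = False
    for _ in range(100):
        eta = X @ coef
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped update
        t = 1.0
        for _ in range(30):
            new = coef + t * step
            ll_new = _loglik(y, X @ new)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        coef, ll_prev, ll = new, ll, ll_new
        if abs(ll - ll_prev) < 1e-10 * (1.0 + abs(ll)):
            converged = True
            break
    _check_separation(y, X, coef, design.columns)

    mu = expit(X @ coef)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = linalg.inv((X * w[:, None]).T @ X)
    return ModelFit(
        coef=coef,
        se=np.sqrt(np.diag(cov)),
        columns=list(design.columns),
        vcomp={},
        loglik=ll,
        k=p,
        n=n,
        converged=converged,
        method="glm",
        meta={"scaling": dict(design.scaling)},
    )


# ---------------------------------------------------------------------------
# GLMM (Laplace)
# ---------------------------------------------------------------------------

def _build_z(groups: Mapping[str, np.ndarray], n: int):
    """Random-intercept indicator matrix and per-column level index."""
    blocks, col_level, levels = [], [], []
    for li, (level, codes) in enumerate(groups.items()):
        q = int(codes.max()) + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        blocks.append(Z)
        col_level.extend([li] * q)
        levels.append(level)
    return np.hstack(blocks), np.asarray(col_level), levels


def _inner_mode(y, C, p, dinv, start, max_iter=200):
    """Maximise the joint penalised log-likelihood over (beta, u)."""
    theta = start.copy()

    def pll(th):
        eta = C @ th
        return _loglik(y, eta) - 0.5 * float(np.sum(dinv * th[p:] ** 2))

    cur = pll(theta)
    for _ in range(max_iter):
        eta = C @ theta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = C.T @ (y - mu)
        grad[p:] -= dinv * theta[p:]
        H = (C * w[:, None]).T @ C
        H[p:, p:] += np.diag(dinv)
        try:
            cf = linalg.cho_factor(H)
            step = linalg.cho_solve(cf, grad)
        except linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            new = theta + t * step
            val = pll(new)
            if val >= cur - 1e-12:
                break
            t /= 2.0
        theta, prev, cur = new, cur, val
        if abs(cur - prev) < 1e-10 * (1.0 + abs(cur)):
            return theta, cur, True
    return theta, cur, False


def _laplace_criterion(y, C, p, dinv, sigma2_cols, theta):
    """-2 x Laplace-approximate marginal log-likelihood at the mode."""
    eta = C @ theta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    Z = C[:, p:]
    Huu = (Z * w[:, None]).T @ Z + np.diag(dinv)
    sign, logdet = np.linalg.slogdet(Huu)
    pll = _loglik(y, eta) - 0.5 * float(np.sum(dinv * theta[p:] ** 2))
    lmarg = pll - 0.5 * logdet - 0.5 * float(np.sum(np.log(sigma2_cols)))
    return -2.0 * lmarg


def fit_logistic_glmm(
    design: LogisticDesign,
    fix_sigma2: Mapping[str, float] | None = None,
    min_log_sd: float = -6.0,
    max_log_sd: float = 3.0,
) -> ModelFit:
    """Approximate-ML binomial GLMM with nested random intercepts.

    Variance components may be pinned via ``fix_sigma2`` (a level -> sigma^2
    mapping); pinning every level at 0 reduces the fit to the plain GLM.
    A variance component driven to (near) zero is flagged ``singular``, not
    an error; non-convergence is flagged, with partial results returned.
    """
    if not design.groups:
        raise ValueError("no grouping levels supplied; use fit_logistic_glm")
    fix_sigma2 = dict(fix_sigma2 or {})
    levels_all = list(design.groups)
    for level in fix_sigma2:
        if level not in design.groups:
            raise KeyError(f"unknown grouping level {level!r}")

    # Levels fixed at exactly zero contribute nothing: drop them from Z.
    active = {
        lvl: codes
        for lvl, codes in design.groups.items()
        if fix_sigma2.get(lvl, None) != 0.0
    }
    if not active:
        base = fit_logistic_glm(design)
        base.method = "glmm"
        base.vcomp = {lvl: 0.0 for lvl in levels_all}
        return base

    y, X = design.y, design.X
    n, p = X.shape
    for lvl, codes in active.items():
        if len(np.unique(codes)) < 2:
            raise ValueError(f"grouping level {lvl!r} has fewer than 2 groups")
    Z, col_level, levels = _build_z(active, n)
    q = Z.shape[1]
    C = np.hstack([X, Z])

    free_levels = [lvl for lvl in levels if lvl not in fix_sigma2]
    fixed_logsd = {
        lvl: 0.5 * math.log(fix_sigma2[lvl]) for lvl in levels if lvl in fix_sigma2
    }

    state = {"theta": np.zeros(p + q), "inner_ok": True}

    def sigma2_for(log_sd_free: np.ndarray) -> np.ndarray:
        out = np.empty(len(levels))
        it = iter(log_sd_free)
        for i, lvl in enumerate(levels):
            ls = fixed_logsd[lvl] if lvl in fixed_logsd else next(it)
            out[i] = math.exp(2.0 * ls)
        return out

    def objective(log_sd_free: np.ndarray) -> float:
        sigma2 = sigma2_for(np.atleast_1d(log_sd_free))
        sigma2_cols = sigma2[col_level]
        dinv = 1.0 / sigma2_cols
        theta, _, ok = _inner_mode(y, C, p, dinv, state["theta"])
        state["theta"] = theta
        state["inner_ok"] = ok
        return _laplace_criterion(y, C, p, dinv, sigma2_cols, theta)

    if free_levels:
        x0 = np.zeros(len(free_levels))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
        best = np.clip(res.x, min_log_sd, max_log_sd)
        outer_ok = bool(res.success)
    else:
        best = np.empty(0)
        outer_ok = True

    sigma2 = sigma2_for(best)
    sigma2_cols = sigma2[col_level]
    dinv = 1.0 / sigma2_cols
    theta, _, inner_ok = _inner_mode(y, C, p, dinv, state["theta"])
    crit = _laplace_criterion(y, C, p, dinv, sigma2_cols, theta)

    eta = C @ theta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (C * w[:, None]).T @ C
    H[p:, p:] += np.diag(dinv)
    cov_full = linalg.inv(H)
    se = np.sqrt(np.diag(cov_full)[:p])

    vcomp = {lvl: 0.0 for lvl in levels_all}
    ranef: dict[str, np.ndarray] = {}
    offset = p
    for i, lvl in enumerate(levels):
        vcomp[lvl] = float(sigma2[i])
        qi = int(np.sum(col_level == i))
        ranef[lvl] = theta[offset : offset + qi].copy()
        offset += qi

    singular = any(vcomp[lvl] < 1e-2 for lvl in free_levels)
    return ModelFit(
        coef=theta[:p].copy(),
        se=se,
        columns=list(design.columns),
        vcomp=vcomp,
        loglik=-0.5 * crit,
        k=p + len(free_levels) + len([l for l in fixed_logsd]),
        n=n,
        converged=bool(outer_ok and inner_ok),
        singular=singular,
        method="glmm",
        random_effects=ranef,
        meta={"scaling": dict(design.scaling)},
    )


# ---------------------------------------------------------------------------
# model comparison & effects
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (got n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Iterable[float]) -> np.ndarray:
    """Normalised model evidence from AICc values (shift-invariant)."""
    vals = np.asarray(list(aicc_values), dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("need at least one finite AICc value")
    delta = vals - np.min(vals[finite])
    raw = np.where(finite, np.exp(-delta / 2.0), 0.0)
    return raw / raw.sum()


def compare_models(
    entries: Sequence[tuple[str, float, int, tuple[str, ...]]],
    n: int,
    auc: Sequence[float | None] | None = None,
    r2: Sequence[float | None] | None = None,
) -> list[ModelComparisonRow]:
    """Build an AICc comparison table from (label, loglik, k, variables)."""
    aiccs = [aicc(ll, k, n) for _, ll, k, _ in entries]
    weights = akaike_weights(aiccs)
    best = min(aiccs)
    rows = []
    for i, (label, ll, k, variables) in enumerate(entries):
        rows.append(
            ModelComparisonRow(
                label=label,
                k=k,
                loglik=ll,
                aicc=aiccs[i],
                delta_aicc=aiccs[i] - best,
                weight=float(weights[i]),
                variables=tuple(variables),
                auc=None if auc is None else auc[i],
                r2=None if r2 is None else r2[i],
            )
        )
    return rows


def relative_importance(rows: Sequence[ModelComparisonRow]) -> dict[str, float]:
    """Per-variable importance: sum of weights of models containing it."""
    out: dict[str, float] = {}
    for row in rows:
        for v in row.variables:
            out[v] = out.get(v, 0.0) + row.weight
    return out


def effect_size_pct(beta0: float, beta1: float) -> float:
    """Published effect-size expression for a one-SD predictor increase.

    Evaluates 1/(1+exp(b0+b1)) - 1/(1+exp(b0+2*b1)) verbatim.  Note this
    uses 1/(1+exp(x)) rather than the standard logistic 1/(1+exp(-x)), so
    only the magnitude is interpretation-safe.
    """
    return float(
        1.0 / (1.0 + math.exp(beta0 + beta1))
        - 1.0 / (1.0 + math.exp(beta0 + 2.0 * beta1))
    )


def r2_glmm(fit: ModelFit, X: np.ndarray | None = None) -> VarianceDecomposition:
    """Marginal/conditional R^2 for a logit-link fit.

    s2_fixed is the variance of the fixed-effect linear predictor over the
    data; s2_random is the sum of the random-intercept variances; the
    logit distribution-specific variance is pi^2/3.
    """
    if X is None:
        raise ValueError("pass the fixed-effect design matrix X")
    eta = np.asarray(X, dtype=float) @ fit.coef
    s2f = float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0
    s2r = float(sum(fit.vcomp.values()))
    return VarianceDecomposition(s2_fixed=s2f, s2_random=s2r)
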