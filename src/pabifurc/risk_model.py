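"""L1-penalised logistic risk score: path fitting, CV lambda selection,
formula export and application.

The solver is a glmnet-style iteratively-reweighted coordinate descent
on internally standardised features, with the intercept left
unpenalised.  Coefficients are reported on the original feature scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoFit",
    "ScoreFormula",
    "PUBLISHED_FORMULA",
    "fit_lasso_cv",
    "select_lambda",
    "extract_formula",
    "apply_formula",
    "lambda_summary",
]

_WMIN = 1e-5  # floor on IRLS weights, as in glmnet


# ------------------------------------------------------------------ types


@dataclass
class ScoreFormula:
    """Sparse linear score: named feature -> weight, optional intercept."""

    weights: Dict[str, float]
    intercept: float = 0.0
    name: str = "fitted"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"weights": self.weights, "intercept": self.intercept, "name": self.name},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ScoreFormula":
        with open(path) as fh:
            d = json.load(fh)
        return cls(weights=d["weights"], intercept=d.get("intercept", 0.0),
                   name=d.get("name", "fitted"))


#: The published three-term score over scaled-unit features
#: (areas in 100 mm^2, diameters in 10 mm); no intercept.
PUBLISHED_FORMULA = ScoreFormula(
    weights={
        "MPA bifurcation area (100 mm2)": 0.92,
        "MPA outlet hydraulic diameter (10 mm)": 0.50,
        "MPA outlet CSA (100 mm2)": 0.10,
    },
    intercept=0.0,
    name="published",
)


@dataclass
class LassoFit:
    """Solution path of the L1 logistic regression plus its CV curves."""

    feature_names: List[str]
    lambdas: np.ndarray            # descending grid
    coefs: np.ndarray              # (n_lambda, p), original feature scale
    intercepts: np.ndarray         # (n_lambda,), original scale
    coefs_std: np.ndarray          # (n_lambda, p), standardised scale
    cv_mean: np.ndarray            # mean CV binomial deviance per lambda
    cv_se: np.ndarray              # standard error across folds
    fold_assignments: np.ndarray   # per-training-row fold index
    seed: int
    dropped_features: List[str] = field(default_factory=list)

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[int(np.argmin(self.cv_mean))])

    @property
    def lambda_1se(self) -> float:
        i_min = int(np.argmin(self.cv_mean))
        bound = self.cv_mean[i_min] + self.cv_se[i_min]
        ok = np.nonzero(self.cv_mean <= bound)[0]
        # grid is descending, so the smallest index is the largest lambda
        return float(self.lambdas[int(ok.min())])

    def coef_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        if not math.isclose(self.lambdas[idx], lam, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"lambda {lam!r} not on the fitted grid")
        return self.coefs[idx]

    def intercept_at(self, lam: float) -> float:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.intercepts[idx])

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "lambdas": self.lambdas.tolist(),
            "coefs": self.coefs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "cv_mean": self.cv_mean.tolist(),
            "cv_se": self.cv_se.tolist(),
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "seed": self.seed,
            "dropped_features": self.dropped_features,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ----------------------------------------------------------------- solver


try:  # compiled coordinate-descent core; plain Python fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap(args[0]) if args and callable(args[0]) else wrap


@_njit(cache=True)
def _cd_core(X, y, lambdas, tol, max_outer):  # pragma: no cover - compiled
    n, p = X.shape
    L = len(lambdas)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    coefs = np.zeros((L, p))
    intercepts = np.zeros(L)
    eta = np.full(n, b0)
    w = np.empty(n)
    z = np.empty(n)
    resid = np.empty(n)
    denom = np.empty(p)

    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_outer):
            wsum = 0.0
            for i in range(n):
                prob = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = prob * (1.0 - prob)
                if wi < _WMIN:
                    wi = _WMIN
                w[i] = wi
                wsum += wi
                z[i] = eta[i] + (y[i] - prob) / wi
                resid[i] = z[i] - eta[i]
            for j in range(p):
                acc = 0.0
                for i in range(n):
                    acc += w[i] * X[i, j] * X[i, j]
                denom[j] = acc / n

            for _cycle in range(10000):
                max_delta = 0.0
                for j in range(p):
                    rho = 0.0
                    for i in range(n):
                        rho += w[i] * X[i, j] * resid[i]
                    rho = rho / n + denom[j] * beta[j]
                    if rho > lam:
                        bj_new = (rho - lam) / denom[j]
                    elif rho < -lam:
                        bj_new = (rho + lam) / denom[j]
                    else:
                        bj_new = 0.0
                    delta = bj_new - beta[j]
                    if delta != 0.0:
                        for i in range(n):
                            resid[i] -= delta * X[i, j]
                        beta[j] = bj_new
                        if abs(delta) > max_delta:
                            max_delta = abs(delta)
                db0 = 0.0
                for i in range(n):
                    db0 += w[i] * resid[i]
                db0 /= wsum
                if db0 != 0.0:
                    b0 += db0
                    for i in range(n):
                        resid[i] -= db0
                    if abs(db0) > max_delta:
                        max_delta = abs(db0)
                if max_delta < 1e-10:
                    break
            for i in range(n):
                eta[i] = z[i] - resid[i]

            # KKT check on the true (non-quadratic) objective
            kkt = 0.0
            gmean = 0.0
            for i in range(n):
                resid[i] = 1.0 / (1.0 + np.exp(-eta[i])) - y[i]  # reuse buffer
                gmean += resid[i]
            gmean = abs(gmean / n)
            if gmean > kkt:
                kkt = gmean
            for j in range(p):
                g = 0.0
                for i in range(n):
                    g += X[i, j] * resid[i]
                g /= n
                if beta[j] > 0.0:
                    v = abs(g + lam)
                elif beta[j] < 0.0:
                    v = abs(g - lam)
                else:
                    v = abs(g) - lam
                    if v < 0.0:
                        v = 0.0
                if v > kkt:
                    kkt = v
            if kkt < tol:
                break
        for j in range(p):
            coefs[li, j] = beta[j]
        intercepts[li] = b0
    return coefs, intercepts


def _cd_logistic_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                      tol: float = 1e-8, max_outer: int = 200) -> tuple:
    """Coordinate-descent path for (1/n) binomial deviance + lambda * ||b||_1.

    ``X`` must already be standardised.  Returns (coefs, intercepts) on
    that standardised scale.  Convergence is checked on the KKT system.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    return _cd_core(X, y, lambdas, float(tol), int(max_outer))


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob)))


# -------------------------------------------------------------- operations


def fit_lasso_cv(
    table: pd.DataFrame,
    feature_columns: Optional[Sequence[str]] = None,
    outcome_column: str = "event",
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-8,
) -> LassoFit:
    """Fit the cross-validated L1 logistic path on a cohort table.

    Folds are stratified on the outcome and fixed by ``seed``; the CV
    loss is the binomial deviance.  Constant features are dropped with a
    warning; a constant outcome is an error.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns
            if c not in (outcome_column, "set") and pd.api.types.is_numeric_dtype(table[c])
        ]
    feature_columns = list(feature_columns)
    y = table[outcome_column].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; cannot fit")

    X = table[feature_columns].to_numpy(dtype=float)
    sds = X.std(axis=0)
    dropped = [c for c, s in zip(feature_columns, sds) if s == 0.0]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}")
        keep = [i for i, s in enumerate(sds) if s != 0.0]
        X = X[:, keep]
        feature_columns = [feature_columns[i] for i in keep]

    Xs, mu, sd = _standardize(X)
    lambdas = _lambda_grid(Xs, y, n_lambdas, lambda_min_ratio)

    coefs_std, b0_std = _cd_logistic_path(Xs, y, lambdas, tol=tol)
    coefs = coefs_std / sd[None, :]
    intercepts = b0_std - coefs @ mu

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assign = np.empty(len(y), dtype=int)
    fold_dev = np.zeros((n_folds, len(lambdas)))
    for k, (tr, te) in enumerate(skf.split(X, y)):
        fold_assign[te] = k
        Xt, mu_t, sd_t = _standardize(X[tr])
        ck, bk = _cd_logistic_path(Xt, y[tr], lambdas, tol=tol)
        Xe = (X[te] - mu_t) / sd_t
        eta = bk[:, None] + ck @ Xe.T  # (n_lambda, n_test)
        prob = 1.0 / (1.0 + np.exp(-eta))
        for li in range(len(lambdas)):
            fold_dev[k, li] = _deviance(y[te], prob[li])
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)

    return LassoFit(
        feature_names=feature_columns,
        lambdas=lambdas,
        coefs=coefs,
        intercepts=intercepts,
        coefs_std=coefs_std,
        cv_mean=cv_mean,
        cv_se=cv_se,
        fold_assignments=fold_assign,
        seed=seed,
        dropped_features=dropped,
    )


def select_lambda(fit: LassoFit, rule: str = "1se") -> float:
    """Pick the penalty by the minimum-deviance or the 1-SE rule."""
    if len(fit.lambdas) == 0:
        raise ValueError("empty lambda grid")
    if rule == "min":
        return fit.lambda_min
    if rule == "1se":
        return fit.lambda_1se
    raise ValueError(f"unknown rule {rule!r}; expected 'min' or '1se'")


def extract_formula(fit: LassoFit, lam: float) -> ScoreFormula:
    """Nonzero original-scale coefficients at ``lam`` as a named formula."""
    beta = fit.coef_at(lam)
    weights = {
        name: float(b) for name, b in zip(fit.feature_names, beta) if b != 0.0
    }
    return ScoreFormula(weights=weights, intercept=fit.intercept_at(lam))


def apply_formula(formula: ScoreFormula, features) -> float:
    """Linear score of one feature vector (dict / Series), scaled units.

    The returned value is exact; round to 2 decimals only for display.
    """
    score = formula.intercept
    for name, w in formula.weights.items():
        try:
            value = features[name]
        except (KeyError, IndexError):
            raise KeyError(f"feature {name!r} missing from input") from None
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise KeyError(f"feature {name!r} missing from input")
        score += w * float(value)
    return float(score)


def apply_formula_frame(formula: ScoreFormula, frame: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`apply_formula` over the rows of a DataFrame."""
    missing = [c for c in formula.weights if c not in frame.columns]
    if missing:
        raise KeyError(f"feature {missing[0]!r} missing from input")
    score = pd.Series(formula.intercept, index=frame.index, dtype=float)
    for name, w in formula.weights.items():
        score = score + w * frame[name].astype(float)
    return score


def lambda_summary(lam: float) -> dict:
    """Report a selected penalty with its natural log at display precision."""
    return {
        "lambda": lam,
        "log_lambda": math.log(lam),
        "log_lambda_2dp": round(math.log(lam), 2),
    }
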