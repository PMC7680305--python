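"""Penalized and conventional models for node-level metastasis prediction.

Radiomic models are L1-penalized (LASSO) logistic regressions: features are
column-standardized, a geometric lambda grid is laid out from lambda_max
(the smallest penalty with an all-zero solution) downward, and the penalty
is chosen by stratified (optionally patient-grouped) 10-fold cross-validated
binomial deviance at its minimum (the "lambda.min" rule; the 1-SE rule is
available as an option).  Conventional single-covariate models (short
diameter, volume, expert rating, SUVmax) are plain maximum-likelihood
logistic fits with Wald odds-ratio intervals and a separation check.

The dichotomization cutpoint for a fitted score is selected on the training
scores by maximally selected rank statistics: among candidate splits in the
inner 10-90% quantile range, the one maximizing the standardized two-sample
Wilcoxon-score statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FittedModel",
    "lasso_logistic_path",
    "cv_select_lambda",
    "fit_lasso_model",
    "fit_conventional",
    "maxstat_cutpoint",
    "MODEL_FEATURE_CLASSES",
]

# radiomic model roster: input feature classes per model
MODEL_FEATURE_CLASSES = {
    "Radiomics-texture": ("texture",),
    "Radiomics-shape": ("shape",),
    "Radiomics-intensity": ("intensity",),
    "Radiomics-LBP": ("lbp",),
    "Radiomics-combined": ("texture", "shape", "intensity", "lbp"),
}


@dataclass
class FittedModel:
    """A fitted (possibly sparse) logistic model on standardized inputs.

    ``score(x) = intercept + sum_i beta_i * (x_i - center_i) / scale_i``
    """

    name: str
    features: list[str]
    intercept: float
    coef: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    lam: float | None = None
    cutpoint: float | None = None
    cv_deviance: pd.DataFrame | None = field(default=None, repr=False)
    warnings: list[str] = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = X[self.features].to_numpy(np.float64) if isinstance(X, pd.DataFrame) else np.asarray(X, np.float64)
        z = (x - self.center[None, :]) / self.scale[None, :]
        return self.intercept + z @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    @property
    def selected_features(self) -> list[str]:
        return [f for f, c in zip(self.features, self.coef) if c != 0.0]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features": self.features,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "lambda": self.lam,
            "cutpoint": self.cutpoint,
            "warnings": self.warnings,
        }


def _standardize(X: np.ndarray):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    keep = scale > 0
    scale_safe = np.where(keep, scale, 1.0)
    return (X - center) / scale_safe, center, scale_safe, keep


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 30,
                min_ratio: float | None = None) -> np.ndarray:
    """Geometric penalty grid from lambda_max downward.

    ``lambda_max = max |X_std^T (y - mean(y))| / n`` is the smallest penalty
    at which all coefficients are zero.
    """
    z, *_ = _standardize(np.asarray(X, np.float64))
    y = np.asarray(y, np.float64)
    n = len(y)
    lam_max = float(np.abs(z.T @ (y - y.mean())).max() / n)
    lam_max = max(lam_max, 1e-6)
    if min_ratio is None:
        min_ratio = 1e-3 if n > z.shape[1] else 1e-2
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_l1(
    z: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8, max_iter: int = 2000
) -> tuple[float, np.ndarray]:
    """One L1-penalized logistic fit on standardized columns.

    Objective (glmnet scale): (1/n) sum loss + lam * ||beta||_1, mapped to
    scikit-learn's C = 1 / (n * lam); the intercept is unpenalized.  The
    iteration cap acts as the floor near separation: coefficients stop
    growing instead of diverging.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    n = len(y)
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
        intercept_scaling=1e4, max_iter=max_iter, tol=tol,
        random_state=0,  # liblinear shuffles features internally
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(z, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def lasso_logistic_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient path of the L1-penalized logistic regression.

    Returns ``(lambdas, intercepts, coefs)`` with ``coefs[k]`` the
    coefficient vector (on standardized inputs) at ``lambdas[k]``.  Constant
    columns are kept in place with zero coefficients.
    """
    X = np.asarray(X, np.float64)
    y = np.asarray(y, np.float64)
    if len(y) < 10:
        raise ValueError("need n >= 10 observations")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    z, _, _, keep = _standardize(X)
    z = z[:, keep]
    intercepts = np.empty(len(lambdas))
    coefs = np.zeros((len(lambdas), X.shape[1]))
    for k, lam in enumerate(lambdas):
        b0, b = _fit_l1(z, y, lam)
        intercepts[k] = b0
        coefs[k, keep] = b
    return np.asarray(lambdas), intercepts, coefs


def _grouped_stratified_folds(y, groups, n_folds, rng) -> np.ndarray:
    """Fold assignment keeping groups intact, roughly balanced in class counts.

    Groups (patients) are sorted by their positive fraction and dealt
    round-robin (in random order within the deal) so every fold sees both
    classes whenever feasible.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    frac = np.array([y[groups == g].mean() for g in uniq])
    order = np.lexsort((rng.random(len(uniq)), frac))
    fold_of_group = {}
    for pos, gi in enumerate(order):
        fold_of_group[uniq[gi]] = pos % n_folds
    return np.array([fold_of_group[g] for g in groups])


def _stratified_folds(y, n_folds, rng) -> np.ndarray:
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def binomial_deviance(y, p) -> float:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cv_select_lambda(
    X, y, n_folds: int = 10, seed: int = 0,
    groups=None, lambdas=None, rule: str = "min",
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty by cross-validated binomial deviance.

    Folds are stratified by class; when ``groups`` (patient IDs) are given,
    whole patients are kept in one fold.  ``rule`` is "min" (default) or
    "1se".  Returns ``(lambda*, cv_table)``; fold assignment is
    seed-deterministic.
    """
    X = np.asarray(X, np.float64)
    y = np.asarray(y, np.float64)
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    rng = np.random.default_rng(seed)
    for _ in range(20):
        if groups is not None:
            folds = _grouped_stratified_folds(y, groups, n_folds, rng)
        else:
            folds = _stratified_folds(y, n_folds, rng)
        ok = all(len(np.unique(y[folds != f])) == 2 for f in range(n_folds))
        if ok:
            break
    else:
        raise ValueError("could not build folds with both classes in every training split")

    dev = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if te.sum() == 0:
            dev[f] = np.nan
            continue
        z, center, scale, keep = _standardize(X[tr])
        zte = (X[te] - center) / scale
        for k, lam in enumerate(lambdas):
            # held-out deviance is insensitive to the last digits of the fit;
            # a lighter tolerance keeps the 10x30 fold/penalty sweep fast
            b0, b = _fit_l1(z[:, keep], y[tr], lam, tol=1e-6, max_iter=500)
            eta = b0 + zte[:, keep] @ b
            dev[f, k] = binomial_deviance(y[te], 1 / (1 + np.exp(-eta)))

    mean_dev = np.nanmean(dev, axis=0)
    se_dev = np.nanstd(dev, axis=0) / np.sqrt(n_folds)
    k_min = int(np.argmin(mean_dev))
    if rule == "1se":
        bound = mean_dev[k_min] + se_dev[k_min]
        k_sel = int(np.argmax(mean_dev <= bound))  # largest lambda within 1 SE
    else:
        k_sel = k_min
    table = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev, "se": se_dev})
    return float(lambdas[k_sel]), table


def fit_lasso_model(
    X: pd.DataFrame, y, name: str, seed: int = 0,
    groups=None, n_folds: int = 10, rule: str = "min",
) -> FittedModel:
    """CV-select the penalty, refit on all training rows, derive the cutpoint."""
    features = list(X.columns)
    xmat = X.to_numpy(np.float64)
    yvec = np.asarray(y, np.float64)
    lams = lambda_grid(xmat, yvec)
    lam, cv_table = cv_select_lambda(
        xmat, yvec, n_folds=n_folds, seed=seed, groups=groups, lambdas=lams, rule=rule
    )
    z, center, scale, keep = _standardize(xmat)
    warnings = []
    if not keep.all():
        warnings.append(f"dropped {int((~keep).sum())} constant feature(s)")
    b0, b = _fit_l1(z[:, keep], yvec, lam)
    coef = np.zeros(len(features))
    coef[keep] = b
    model = FittedModel(
        name=name, features=features, intercept=b0, coef=coef,
        center=center, scale=scale, lam=lam, cv_deviance=cv_table,
        warnings=warnings,
    )
    scores = model.linear_predictor(X)
    try:
        model.cutpoint = maxstat_cutpoint(scores, yvec)
    except ValueError:
        # all-tied scores (e.g. null model): fall back to the score median
        model.cutpoint = float(np.median(scores))
        model.warnings.append("degenerate scores; cutpoint set to median")
    return model


# ---------------------------------------------------------------------------
# conventional (unpenalized) logistic models
# ---------------------------------------------------------------------------

def fit_conventional(
    X: pd.DataFrame, y, name: str = "conventional", alpha: float = 0.05
) -> tuple[FittedModel, pd.DataFrame]:
    """Maximum-likelihood logistic fit with odds ratios and Wald CIs.

    Accepts one covariate (univariate mode) or several (multivariate mode).
    Quasi-separation is detected from exploding standard errors; the
    affected covariate's CI is reported as (0, inf) and flagged unstable,
    matching how such fits surface in practice.
    """
    import warnings as _warnings

    import scipy.stats as st
    import statsmodels.api as sm

    features = list(X.columns)
    xmat = X.to_numpy(np.float64)
    yvec = np.asarray(y, np.float64)
    z, center, scale, keep = _standardize(xmat)
    exog = sm.add_constant(z[:, keep])
    unstable = False
    # separation is detected below from the standard errors; statsmodels'
    # own warnings about it would only repeat that
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yvec, exog).fit(disp=0, maxiter=200)
            params, bse = res.params, res.bse
            converged = res.mle_retvals.get("converged", True)
        except Exception:
            res = sm.Logit(yvec, exog).fit(method="bfgs", disp=0, maxiter=500)
            params, bse = res.params, res.bse
            converged = False
    if not converged or not np.all(np.isfinite(bse)) or np.nanmax(bse) > 50:
        unstable = True

    zcrit = st.norm.ppf(1 - alpha / 2)
    rows = []
    j = 1
    for i, f in enumerate(features):
        if not keep[i]:
            rows.append({"covariate": f, "odds_ratio": 1.0, "ci_low": 0.0,
                         "ci_high": np.inf, "p_value": 1.0, "unstable": True})
            continue
        beta, se = params[j], bse[j]
        # exploding SE or coefficient signals (quasi-)separation; the Wald
        # interval is then meaningless and reported unbounded
        flag = (not np.isfinite(se)) or se > 10 or abs(beta) > 10 or not converged
        if flag:
            lo, hi, p = 0.0, np.inf, 1.0
        else:
            lo = float(np.exp(beta - zcrit * se))
            hi = float(np.exp(beta + zcrit * se))
            p = float(2 * st.norm.sf(abs(beta / se)))
        rows.append({"covariate": f, "odds_ratio": float(np.exp(beta)),
                     "ci_low": lo, "ci_high": hi, "p_value": p, "unstable": flag})
        j += 1

    coef = np.zeros(len(features))
    coef[keep] = params[1:]
    model = FittedModel(
        name=name, features=features, intercept=float(params[0]), coef=coef,
        center=center, scale=scale,
        warnings=(["possible separation; Wald inference unstable"] if unstable else []),
    )
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------

def maxstat_cutpoint(
    scores, y, min_prop: float = 0.1, max_prop: float = 0.9,
    return_stat: bool = False,
):
    """Optimal dichotomization cutpoint by maximally selected rank statistics.

    Candidate splits are the midpoints between consecutive distinct score
    values whose left-group proportion lies in [min_prop, max_prop].  For
    each candidate the standardized two-sample linear rank statistic with
    Wilcoxon (midrank) scores of the outcome is computed; the returned
    cutpoint maximizes its absolute value.
    """
    s = np.asarray(scores, np.float64)
    yv = np.asarray(y, np.float64)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("all scores tied; no cutpoint exists")
    if len(np.unique(yv)) < 2:
        raise ValueError("both outcome classes must be present")

    n = len(s)
    import scipy.stats as st

    a = st.rankdata(yv)          # midranks of the outcome
    abar, avar = a.mean(), a.var(ddof=1)
    best, best_stat = None, -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        left = s <= cut
        n1 = int(left.sum())
        prop = n1 / n
        if prop < min_prop or prop > max_prop:
            continue
        stat_num = a[left].sum() - n1 * abar
        var = n1 * (n - n1) * avar / n
        if var <= 0:
            continue
        stat = abs(stat_num) / np.sqrt(var)
        if stat > best_stat:
            best, best_stat = cut, stat
    if best is None:
        raise ValueError("no admissible split in the inner proportion range")
    return (float(best), float(best_stat)) if return_stat else float(best)
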