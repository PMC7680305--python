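"""Parametric empirical-Bayes batch harmonization (ComBat) of feature tables.

The location/scale model: for feature g, sample j of batch i,

    y_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg

After standardizing each feature by its grand mean and pooled variance, the
per-batch location gamma and scale delta^2 are estimated and then shrunk
toward the across-feature batch priors (normal prior for gamma, inverse-gamma
for delta^2) with the standard iterative empirical-Bayes updates.  The
adjusted value is

    y* = (z - gamma*) / delta* * pooled_sd + grand_mean

Harmonization is label-blind: no biological covariates enter the design,
which is a caveat when batches are confounded with outcome.  Batch labels
unseen at fit time raise, never pass through silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CombatParams", "combat_fit", "combat_apply"]


@dataclass
class CombatParams:
    """Fitted ComBat parameters (everything needed to adjust new rows)."""

    features: list[str]
    batches: list[str]
    grand_mean: np.ndarray          # (G,)
    pooled_var: np.ndarray          # (G,)
    gamma_star: dict[str, np.ndarray]   # batch -> (G,)
    delta2_star: dict[str, np.ndarray]  # batch -> (G,)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "batches": self.batches,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": {b: v.tolist() for b, v in self.gamma_star.items()},
            "delta2_star": {b: v.tolist() for b, v in self.delta2_star.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombatParams":
        return cls(
            features=list(d["features"]),
            batches=list(d["batches"]),
            grand_mean=np.asarray(d["grand_mean"]),
            pooled_var=np.asarray(d["pooled_var"]),
            gamma_star={b: np.asarray(v) for b, v in d["gamma_star"].items()},
            delta2_star={b: np.asarray(v) for b, v in d["delta2_star"].items()},
        )


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2.0 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else 1.0


def _it_solve(z_batch, g_hat, d2_hat, g_bar, t2, a, b, tol=1e-6, max_iter=100):
    """Iterative EB posterior updates for one batch (vector over features)."""
    n = z_batch.shape[0]
    g_new, d2_new = g_hat.copy(), d2_hat.copy()
    for _ in range(max_iter):
        g_old, d2_old = g_new.copy(), d2_new.copy()
        g_new = (t2 * n * g_hat + d2_new * g_bar) / (t2 * n + d2_new)
        sse = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (0.5 * sse + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d2_new - d2_old).max() / max(np.abs(d2_old).max(), 1e-12),
        )
        if change < tol:
            break
    return g_new, d2_new


def combat_fit(features: pd.DataFrame, batch: pd.Series | np.ndarray) -> CombatParams:
    """Estimate ComBat parameters from a feature table and its batch labels.

    Every batch needs at least 2 rows; missing values are not allowed.
    With a single batch the standardized data are already batch-centered, so
    gamma* ~ 0 and delta2* ~ 1 and adjustment is a near-no-op.
    """
    x = features.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains missing or non-finite values")
    batch = np.asarray(batch).astype(str)
    if len(batch) != len(x):
        raise ValueError("batch labels must match rows")
    labels = sorted(set(batch.tolist()))
    for b in labels:
        if (batch == b).sum() < 2:
            raise ValueError(f"batch '{b}' has fewer than 2 samples")

    n = len(x)
    n_per = {b: int((batch == b).sum()) for b in labels}

    # weighted grand mean and pooled variance of the batch-effect model
    batch_means = {b: x[batch == b].mean(axis=0) for b in labels}
    grand_mean = sum(n_per[b] * batch_means[b] for b in labels) / n
    resid = x - np.vstack([batch_means[b] for b in batch])
    pooled_var = (resid**2).sum(axis=0) / n
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)
    pooled_sd = np.sqrt(pooled_var)

    z = (x - grand_mean[None, :]) / pooled_sd[None, :]

    gamma_star, delta2_star = {}, {}
    for b in labels:
        zb = z[batch == b]
        g_hat = zb.mean(axis=0)
        d2_hat = zb.var(axis=0, ddof=1)
        d2_hat = np.where(d2_hat <= 0, 1e-12, d2_hat)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        if t2 <= 0 or len(labels) == 1:
            # nothing to shrink across; keep the direct estimates.  With a
            # single batch use the population variance so fit+apply is an
            # exact no-op on the fitted rows.
            if len(labels) == 1:
                d2_hat = zb.var(axis=0, ddof=0)
                d2_hat = np.where(d2_hat <= 0, 1e-12, d2_hat)
            gamma_star[b], delta2_star[b] = g_hat, d2_hat
            continue
        a, bp = _aprior(d2_hat), _bprior(d2_hat)
        gamma_star[b], delta2_star[b] = _it_solve(zb, g_hat, d2_hat, g_bar, t2, a, bp)

    return CombatParams(
        features=list(features.columns),
        batches=labels,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
    )


def combat_apply(
    features: pd.DataFrame, batch: pd.Series | np.ndarray, params: CombatParams
) -> pd.DataFrame:
    """Adjust a feature table with fitted ComBat parameters.

    Raises ``ValueError`` for batches not seen at fit time.
    """
    if list(features.columns) != params.features:
        raise ValueError("feature columns differ from the fitted table")
    batch = np.asarray(batch).astype(str)
    unseen = sorted(set(batch.tolist()) - set(params.batches))
    if unseen:
        raise ValueError(f"batches not seen at fit time: {unseen}")

    x = features.to_numpy(dtype=np.float64)
    pooled_sd = np.sqrt(params.pooled_var)
    z = (x - params.grand_mean[None, :]) / pooled_sd[None, :]
    out = np.empty_like(z)
    for b in params.batches:
        rows = batch == b
        if not rows.any():
            continue
        out[rows] = (z[rows] - params.gamma_star[b][None, :]) / np.sqrt(
            params.delta2_star[b]
        )[None, :]
    adjusted = out * pooled_sd[None, :] + params.grand_mean[None, :]
    return pd.DataFrame(adjusted, index=features.index, columns=features.columns)
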