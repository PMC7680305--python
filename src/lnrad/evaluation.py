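"""Model evaluation: ROC/AUC, bootstrap CIs, paired comparison, confusion
metrics, calibration, univariate screening and decision-curve analysis.

AUC is the Mann-Whitney concordance probability with ties counted 1/2, so it
is invariant under any strictly monotone transform of the scores.  Bootstrap
intervals resample within each class (stratified) to avoid single-class
replicates with small negative groups.  Decision curves work at the
lymph-node level: one treat/spare decision per node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "roc_auc",
    "bootstrap_auc_ci",
    "ROCResult",
    "compare_auc_paired",
    "ConfusionMetrics",
    "confusion_metrics",
    "reconstruct_confusion",
    "calibration_curve",
    "DecisionCurve",
    "decision_curve",
    "univariate_screen",
    "spearman_to_volume",
]


def roc_auc(scores, y) -> float:
    """AUC as the tie-corrected Mann-Whitney concordance probability."""
    s = np.asarray(scores, np.float64)
    yv = np.asarray(y)
    pos, neg = s[yv == 1], s[yv == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    r = st.rankdata(s)
    u = r[yv == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int
    roc_points: pd.DataFrame | None = None


def roc_points(scores, y) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def bootstrap_auc_ci(
    scores, y, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> ROCResult:
    """Percentile bootstrap CI for the AUC, resampling within each class."""
    s = np.asarray(scores, np.float64)
    yv = np.asarray(y)
    point = roc_auc(s, yv)
    rng = np.random.default_rng(seed)
    ipos, ineg = np.flatnonzero(yv == 1), np.flatnonzero(yv == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(ipos, len(ipos))
        bn = rng.choice(ineg, len(ineg))
        idx = np.concatenate([bp, bn])
        aucs[b] = roc_auc(s[idx], yv[idx])
    alpha = (1 - level) / 2
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    lo, hi = min(lo, point), max(hi, point)  # percentile CI contains the estimate
    return ROCResult(
        auc=point, ci_low=float(lo), ci_high=float(hi),
        level=level, n_boot=n_boot, seed=seed, roc_points=roc_points(s, yv),
    )


def compare_auc_paired(
    scores_a, scores_b, y, n_boot: int = 2000, seed: int = 0
) -> float:
    """Two-sided paired test of AUC(A) = AUC(B) on the same observations.

    A paired bootstrap of the AUC difference (resampling nodes within each
    class, scoring both models on the same replicate) yields the two-sided
    p-value from the sign distribution of the difference.  Identical score
    vectors return p = 1; the test is symmetric in A and B.
    """
    a = np.asarray(scores_a, np.float64)
    b = np.asarray(scores_b, np.float64)
    yv = np.asarray(y)
    if len(a) != len(b) or len(a) != len(yv):
        raise ValueError("paired comparison needs aligned vectors")
    if np.array_equal(a, b):
        return 1.0
    rng = np.random.default_rng(seed)
    ipos, ineg = np.flatnonzero(yv == 1), np.flatnonzero(yv == 0)
    diffs = np.empty(n_boot)
    for k in range(n_boot):
        idx = np.concatenate([rng.choice(ipos, len(ipos)), rng.choice(ineg, len(ineg))])
        diffs[k] = roc_auc(a[idx], yv[idx]) - roc_auc(b[idx], yv[idx])
    # two-sided p from the bootstrap null of zero difference
    p_low = (np.sum(diffs <= 0) + 1) / (n_boot + 1)
    p_high = (np.sum(diffs >= 0) + 1) / (n_boot + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float
    balanced_accuracy: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "PPV": self.ppv, "NPV": self.npv, "MCC": self.mcc,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / np.sqrt(denom)
    return ConfusionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        mcc=float(mcc), balanced_accuracy=(sens + spec) / 2.0,
        degenerate=degenerate,
    )


def confusion_metrics(pred, y) -> ConfusionMetrics:
    """All confusion-table metrics of a binary prediction vector."""
    p = np.asarray(pred).astype(int)
    yv = np.asarray(y).astype(int)
    tp = int(((p == 1) & (yv == 1)).sum())
    fp = int(((p == 1) & (yv == 0)).sum())
    fn = int(((p == 0) & (yv == 1)).sum())
    tn = int(((p == 0) & (yv == 0)).sum())
    return _metrics_from_counts(tp, fp, fn, tn)


def reconstruct_confusion(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMetrics:
    """Rebuild the integer 2x2 table implied by printed sensitivity/specificity.

    ``TP = round(sens * n_pos)``, ``TN = round(spec * n_neg)``; FN/FP by
    complement.  Lets printed classification metrics be checked for internal
    consistency against the class counts.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("counts must be >= 1")
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    return _metrics_from_counts(tp, n_neg - tn, n_pos - tp, tn)


def calibration_curve(probabilities, y, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability bins on [0, 1]; empty bins are omitted."""
    p = np.asarray(probabilities, np.float64)
    yv = np.asarray(y, np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "mean_predicted": float(p[sel].mean()),
                "observed_fraction": float(yv[sel].mean()),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DecisionCurve:
    table: pd.DataFrame  # columns: threshold, nb_model, nb_all, nb_none


def decision_curve(probabilities, y, thresholds=None) -> DecisionCurve:
    """Net benefit NB(p_t) = TP/n - FP/n * p_t/(1-p_t) over a threshold grid.

    A node is treated when its predicted probability is >= p_t.  The
    reference strategies are included: treat-none (identically 0) and
    treat-all (pi - (1-pi) * p_t/(1-p_t) with prevalence pi).
    """
    p = np.asarray(probabilities, np.float64)
    yv = np.asarray(y, np.float64)
    if thresholds is None:
        thresholds = np.arange(0.0, 0.96, 0.01)
    thresholds = np.asarray(thresholds, np.float64)
    if np.any((thresholds < 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in [0, 1)")
    n = len(yv)
    pi = yv.mean()
    rows = []
    for t in thresholds:
        treat = p >= t
        tp = float((treat & (yv == 1)).sum()) / n
        fp = float((treat & (yv == 0)).sum()) / n
        w = t / (1.0 - t)
        rows.append(
            {
                "threshold": float(t),
                "nb_model": tp - fp * w,
                "nb_all": pi - (1 - pi) * w,
                "nb_none": 0.0,
            }
        )
    return DecisionCurve(table=pd.DataFrame(rows))


def univariate_screen(features: pd.DataFrame, y) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum screen with Bonferroni adjustment.

    Exact enumeration is used for tiny groups (scipy switches automatically
    below its threshold when there are no ties); the adjusted p is
    ``min(1, m * p)`` with m the number of features tested.  Constant
    features get p = 1 and a degenerate flag.
    """
    yv = np.asarray(y).astype(int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    m = features.shape[1]
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(np.float64)
        a, b = x[yv == 1], x[yv == 0]
        if np.allclose(x.std(), 0.0):
            p = 1.0
            degenerate = True
        else:
            p = float(st.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            degenerate = False
        rows.append(
            {
                "feature": col,
                "p_value": p,
                "p_adjusted": min(1.0, m * p),
                "significant": min(1.0, m * p) < 0.05,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def spearman_to_volume(
    features: pd.DataFrame, volume, threshold: float = 0.6
) -> pd.DataFrame:
    """Spearman rank correlation (midrank ties) of every feature to volume."""
    v = np.asarray(volume, np.float64)
    if len(v) < 3:
        raise ValueError("need at least 3 nodes")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(np.float64)
        if np.allclose(x.std(), 0.0) or np.allclose(v.std(), 0.0):
            rho, undef = np.nan, True
        else:
            rho = float(st.spearmanr(x, v).statistic)
            undef = False
        rows.append(
            {
                "feature": col,
                "rho": rho,
                "correlated": (abs(rho) >= threshold) if not undef else False,
                "undefined": undef,
            }
        )
    return pd.DataFrame(rows)
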