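"""End-to-end analysis pipeline.

Stages: cohort (synthetic or from disk) -> isotropic resampling and feature
extraction -> univariate statistics -> ICC robustness filtering (training
rater pairs only) -> ComBat scanner harmonization -> LASSO radiomic models +
conventional logistic baselines (trained on the training cohort only; the
penalty, standardization constants and maxstat cutpoint are frozen before
the test cohort is touched) -> evaluation (ROC/AUC with bootstrap CI,
confusion metrics at the training cutpoint, calibration, decision curve,
paired AUC comparisons).

Train/test hygiene: the only quantity estimated across both cohorts is the
ComBat batch adjustment (label-blind, matching how multicenter radiomics
tables are harmonized before modeling); a train-only ComBat mode exists but
requires every test scanner to appear in training.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .combat import combat_apply, combat_fit
from .evaluation import (
    bootstrap_auc_ci,
    compare_auc_paired,
    confusion_metrics,
    calibration_curve,
    decision_curve,
    roc_auc,
    spearman_to_volume,
    univariate_screen,
)
from .images import read_mask, read_volume
from .modeling import (
    MODEL_FEATURE_CLASSES,
    FittedModel,
    fit_conventional,
    fit_lasso_model,
    maxstat_cutpoint,
)
from .panel import PANEL_NAMES, ExtractionConfig, extract_panel, feature_class
from .phantom import PhantomConfig, SyntheticNode, cohort_metadata, generate_cohort
from .reproducibility import RobustnessReport, dice, filter_features

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "extract_cohort_features",
           "load_cohort_dir", "CONVENTIONAL_MODELS"]

CONVENTIONAL_MODELS = {
    "LN-short-diameter": "short_diameter_mm",
    "LN-volume": "volume_mm3",
    "expert-rating": "expert_rating",
    "SUVmax": "suvmax",
}

METADATA_COLS = [
    "patient_id", "node_id", "cohort", "batch", "label",
    "short_diameter_mm", "expert_rating", "suvmax", "volume_mm3", "has_rater2",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; all stochastic stages draw from ``seed``."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    data_dir: str | None = None          # load volumes+masks+metadata.csv instead
    icc_threshold: float = 0.8
    combat: bool = True
    combat_mode: str = "joint"           # "joint" | "train_only"
    grouped_folds: bool = True           # keep a patient's nodes in one CV fold
    n_folds: int = 10
    lambda_rule: str = "min"
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None
    make_plots: bool = False


@dataclass
class PipelineResult:
    features: pd.DataFrame               # metadata + 156 features, one row per node
    robustness: RobustnessReport
    rater_dice: pd.DataFrame
    univariate: pd.DataFrame
    volume_correlation: pd.DataFrame
    models: dict[str, FittedModel]
    conventional_tables: dict[str, pd.DataFrame]
    evaluation: dict
    combat_params: object | None = None

    def auc(self, model: str, cohort: str = "test") -> float:
        return self.evaluation["models"][model][cohort]["auc"]


# ---------------------------------------------------------------------------
# feature extraction over a cohort
# ---------------------------------------------------------------------------

def extract_cohort_features(
    nodes: list[SyntheticNode], cfg: ExtractionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Extract the 156-feature panel for every node.

    Returns ``(features, paired1, paired2, rater_dice)``: the full table
    (metadata + features, rater-1 masks) and the aligned rater-1/rater-2
    feature tables plus per-node Dice for the double-segmented subset.
    """
    cfg = cfg or ExtractionConfig()
    meta = cohort_metadata(nodes)
    feats, p1, p2, dice_rows = [], [], [], []
    for node in nodes:
        try:
            f = extract_panel(node.image, node.mask_rater1, cfg)
        except ValueError as err:
            raise ValueError(f"feature extraction failed for node {node.node_id}: {err}") from err
        feats.append(f)
        if node.mask_rater2 is not None:
            f2 = extract_panel(node.image, node.mask_rater2, cfg)
            p1.append(f)
            p2.append(f2)
            dice_rows.append(
                {"node_id": node.node_id,
                 "dice": dice(node.mask_rater1, node.mask_rater2)}
            )
    features = pd.concat([meta, pd.DataFrame(feats)], axis=1)
    return (
        features,
        pd.DataFrame(p1),
        pd.DataFrame(p2),
        pd.DataFrame(dice_rows, columns=["node_id", "dice"]),
    )


def load_cohort_dir(data_dir: str, cfg: ExtractionConfig | None = None):
    """Feature extraction from a directory of volumes, masks and metadata.csv.

    metadata.csv must carry the METADATA_COLS (minus has_rater2) plus
    ``image``, ``mask`` and optional ``mask_rater2`` path columns (NRRD or
    NIfTI, relative to the directory).
    """
    cfg = cfg or ExtractionConfig()
    meta = pd.read_csv(os.path.join(data_dir, "metadata.csv"))
    feats, p1, p2, dice_rows = [], [], [], []
    has2 = []
    for _, row in meta.iterrows():
        image = read_volume(os.path.join(data_dir, row["image"]))
        mask = read_mask(os.path.join(data_dir, row["mask"]))
        f = extract_panel(image, mask, cfg)
        feats.append(f)
        m2path = row.get("mask_rater2")
        if isinstance(m2path, str) and m2path:
            mask2 = read_mask(os.path.join(data_dir, m2path))
            p1.append(f)
            p2.append(extract_panel(image, mask2, cfg))
            dice_rows.append({"node_id": row["node_id"], "dice": dice(mask, mask2)})
            has2.append(True)
        else:
            has2.append(False)
    meta = meta.drop(columns=[c for c in ("image", "mask", "mask_rater2") if c in meta], errors="ignore")
    meta["has_rater2"] = has2
    features = pd.concat([meta.reset_index(drop=True), pd.DataFrame(feats)], axis=1)
    return features, pd.DataFrame(p1), pd.DataFrame(p2), pd.DataFrame(dice_rows, columns=["node_id", "dice"])


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _evaluate_model(
    name: str, scores_tr, y_tr, scores_te, y_te, cutpoint: float,
    n_boot: int, seed: int,
) -> dict:
    out = {}
    for cohort, s, yv in (("train", scores_tr, y_tr), ("test", scores_te, y_te)):
        ci = bootstrap_auc_ci(s, yv, n_boot=n_boot, seed=seed)
        out[cohort] = {"auc": ci.auc, "ci": [ci.ci_low, ci.ci_high], "n": int(len(yv))}
    cm = confusion_metrics(np.asarray(scores_te) >= cutpoint, y_te)
    out["test"]["confusion"] = cm.to_dict()
    out["cutpoint"] = cutpoint
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole analysis; deterministic given the config."""
    rng_seed = int(config.seed)

    # ----- cohort & features ------------------------------------------------
    if config.data_dir is not None:
        features, paired1, paired2, rater_dice = load_cohort_dir(
            config.data_dir, config.extraction)
    else:
        phantom = config.phantom
        if phantom.seed != rng_seed:
            phantom = replace(phantom, seed=rng_seed)
        nodes = generate_cohort(phantom)
        features, paired1, paired2, rater_dice = extract_cohort_features(
            nodes, config.extraction)

    feat_cols = [c for c in features.columns if c in PANEL_NAMES]
    train = features[features.cohort == "train"].reset_index(drop=True)
    test = features[features.cohort == "test"].reset_index(drop=True)

    # ----- univariate statistics -------------------------------------------
    univariate = univariate_screen(features[feat_cols], features["label"])
    volume_corr = spearman_to_volume(features[feat_cols], features["volume_mm3"])

    # ----- ICC robustness filtering (training rater pairs only) -------------
    robustness = filter_features(paired1, paired2, threshold=config.icc_threshold)
    retained = robustness.retained

    # ----- ComBat harmonization ---------------------------------------------
    combat_params = None
    if config.combat:
        if config.combat_mode == "train_only":
            combat_params = combat_fit(train[feat_cols], train["batch"])
        else:
            combat_params = combat_fit(features[feat_cols], features["batch"])
        train = train.copy()
        test = test.copy()
        train[feat_cols] = combat_apply(train[feat_cols], train["batch"], combat_params)
        test[feat_cols] = combat_apply(test[feat_cols], test["batch"], combat_params)

    y_tr = train["label"].to_numpy(int)
    y_te = test["label"].to_numpy(int)
    groups = train["patient_id"].to_numpy() if config.grouped_folds else None

    models: dict[str, FittedModel] = {}
    conventional_tables: dict[str, pd.DataFrame] = {}
    evaluation: dict = {"models": {}, "comparisons": {}}

    # ----- radiomic LASSO models --------------------------------------------
    for name, classes in MODEL_FEATURE_CLASSES.items():
        cols = [f for f in retained if feature_class(f) in classes]
        if not cols:
            raise ValueError(f"no retained features for model {name}")
        model = fit_lasso_model(
            train[cols], y_tr, name=name, seed=rng_seed, groups=groups,
            n_folds=config.n_folds, rule=config.lambda_rule,
        )
        models[name] = model
        evaluation["models"][name] = _evaluate_model(
            name,
            model.linear_predictor(train[cols]), y_tr,
            model.linear_predictor(test[cols]), y_te,
            model.cutpoint, config.n_boot, rng_seed,
        )

    # ----- conventional baselines -------------------------------------------
    for name, col in CONVENTIONAL_MODELS.items():
        X_tr = train[[col]].astype(float)
        X_te = test[[col]].astype(float)
        model, table = fit_conventional(X_tr, y_tr, name=name)
        s_tr = model.linear_predictor(X_tr)
        try:
            model.cutpoint = maxstat_cutpoint(s_tr, y_tr)
        except ValueError:
            model.cutpoint = float(np.median(s_tr))
        models[name] = model
        conventional_tables[name] = table
        evaluation["models"][name] = _evaluate_model(
            name, s_tr, y_tr, model.linear_predictor(X_te), y_te,
            model.cutpoint, config.n_boot, rng_seed,
        )

    # ----- test-set logistic regression of the combined score (Table-3 style)
    test_uni = {}
    combined_cols = models["Radiomics-combined"].features
    test_covs = {
        "expert-rating": test["expert_rating"].astype(float),
        "LN-short-diameter": test["short_diameter_mm"].astype(float),
        "LN-volume": test["volume_mm3"].astype(float),
        "Radiomics-combined": pd.Series(
            models["Radiomics-combined"].linear_predictor(test[combined_cols]),
            index=test.index),
    }
    for name, cov in test_covs.items():
        _, tbl = fit_conventional(pd.DataFrame({name: cov}), y_te, name=f"test-uni-{name}")
        test_uni[name] = tbl.iloc[0].to_dict()
    evaluation["test_univariate"] = test_uni

    # ----- paired AUC comparisons on the test set ---------------------------
    s_comb = models["Radiomics-combined"].linear_predictor(test[combined_cols])
    for other in ("Radiomics-LBP", "Radiomics-intensity", "Radiomics-texture",
                  "Radiomics-shape", "LN-short-diameter"):
        m = models[other]
        cols = m.features
        s_other = m.linear_predictor(test[cols])
        evaluation["comparisons"][f"Radiomics-combined vs {other}"] = compare_auc_paired(
            s_comb, s_other, y_te, seed=rng_seed)

    # ----- calibration + decision curve for the combined model --------------
    p_te = models["Radiomics-combined"].predict_proba(test[combined_cols])
    evaluation["calibration"] = calibration_curve(p_te, y_te).to_dict("records")
    dc = decision_curve(p_te, y_te)
    p_diam = models["LN-short-diameter"].predict_proba(test[["short_diameter_mm"]].astype(float))
    dc_diam = decision_curve(p_diam, y_te)
    dc.table["nb_short_diameter"] = dc_diam.table["nb_model"]
    evaluation["decision_curve"] = dc.table.to_dict("records")
    evaluation["rater_dice_median"] = (
        float(rater_dice["dice"].median()) if len(rater_dice) else float("nan"))
    evaluation["icc_exclusion_fractions"] = {
        cls: robustness.exclusion_fraction(cls)
        for cls in ("shape", "intensity", "texture", "lbp")
    }
    evaluation["seed"] = rng_seed

    result = PipelineResult(
        features=features,
        robustness=robustness,
        rater_dice=rater_dice,
        univariate=univariate,
        volume_correlation=volume_corr,
        models=models,
        conventional_tables=conventional_tables,
        evaluation=evaluation,
        combat_params=combat_params,
    )
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    result.features.to_csv(os.path.join(out, "features.csv"), index=False)
    result.robustness.table.to_csv(os.path.join(out, "robustness.csv"), index=False)
    result.rater_dice.to_csv(os.path.join(out, "rater_dice.csv"), index=False)
    result.univariate.to_csv(os.path.join(out, "univariate_wilcoxon.csv"), index=False)
    result.volume_correlation.to_csv(os.path.join(out, "volume_spearman.csv"), index=False)
    os.makedirs(os.path.join(out, "models"), exist_ok=True)
    for name, model in result.models.items():
        with open(os.path.join(out, "models", f"{name}.json"), "w") as fh:
            json.dump(model.to_dict(), fh, indent=1)
    if result.combat_params is not None:
        with open(os.path.join(out, "combat_params.json"), "w") as fh:
            json.dump(result.combat_params.to_dict(), fh)
    with open(os.path.join(out, "evaluation.json"), "w") as fh:
        json.dump(result.evaluation, fh, indent=1, default=float)
    if config.make_plots:
        _plots(result, out)


def _plots(result: PipelineResult, out: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    dc = pd.DataFrame(result.evaluation["decision_curve"])
    ax.plot(dc.threshold, dc.nb_model, label="Radiomics-combined")
    ax.plot(dc.threshold, dc.nb_short_diameter, label="LN short diameter")
    ax.plot(dc.threshold, dc.nb_all, "--", label="treat all")
    ax.plot(dc.threshold, dc.nb_none, ":", label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(-0.1, max(0.9, dc.nb_model.max() + 0.05))
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out, "decision_curve.png"), dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    cal = pd.DataFrame(result.evaluation["calibration"])
    ax.plot([0, 1], [0, 1], "--", color="gray")
    ax.plot(cal.mean_predicted, cal.observed_fraction, "o-")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed fraction")
    fig.tight_layout()
    fig.savefig(os.path.join(out, "calibration.png"), dpi=120)
    plt.close(fig)
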