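"""Fit the combined radiomic LASSO model and derive its decision cutpoint.

The penalty lambda is chosen by 10-fold cross-validated binomial deviance
with patient-grouped folds (all nodes of a patient stay in one fold); the
dichotomization cutpoint is selected on the training scores by maximally
selected rank statistics.
"""

from lnrad import (
    PhantomConfig,
    extract_cohort_features,
    fit_lasso_model,
    generate_cohort,
    maxstat_cutpoint,
    roc_auc,
)
from lnrad.panel import PANEL_NAMES

nodes = generate_cohort(PhantomConfig(
    n_patients_train=20, n_patients_test=2, rater2_n_patients=0, seed=13))
features, *_ = extract_cohort_features(nodes)
train = features[features.cohort == "train"]
X = train[[c for c in features.columns if c in PANEL_NAMES]]
y = train.label.to_numpy()

model = fit_lasso_model(X, y, name="Radiomics-combined", seed=13,
                        groups=train.patient_id.to_numpy())
print(f"lambda* = {model.lam:.4f} selected by grouped 10-fold CV")
print(f"{len(model.selected_features)} of {X.shape[1]} features kept:")
for f in model.selected_features[:10]:
    coef = dict(zip(model.features, model.coef))[f]
    print(f"  {f:32s} beta = {coef:+.3f}")

scores = model.linear_predictor(X)
print(f"\ntraining AUC {roc_auc(scores, y):.3f}")
print(f"maxstat cutpoint on the linear predictor: {model.cutpoint:.3f}")
print("scores above the cutpoint are called metastatic when the model is")
print("used as a binary classifier on new nodes.")
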