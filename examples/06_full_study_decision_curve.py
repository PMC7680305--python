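"""Run the complete analysis and read the decision curve.

Everything end to end: cohort, extraction, ICC filtering, ComBat, the five
radiomic models plus four conventional baselines, held-out evaluation and
the lymph-node-level decision curve (one treat/spare decision per node).
Uses a reduced cohort so the whole script runs in well under a minute.
"""

import pandas as pd

from lnrad import PhantomConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    phantom=PhantomConfig(n_patients_train=16, n_patients_test=10,
                          rater2_n_patients=8, seed=2),
    n_boot=200, seed=2,
)
result = run_pipeline(config)

print("held-out (test-cohort) AUC per model:")
for name, rep in result.evaluation["models"].items():
    lo, hi = rep["test"]["ci"]
    print(f"  {name:22s} {rep['test']['auc']:.3f}  (95% CI {lo:.2f}-{hi:.2f})")

dc = pd.DataFrame(result.evaluation["decision_curve"])
rows = dc[dc.threshold.isin([0.2, 0.4, 0.6, 0.8])]
print("\nnet benefit (per node) along the threshold-probability grid:")
print(rows[["threshold", "nb_model", "nb_short_diameter", "nb_all"]]
      .round(3).to_string(index=False))
print("\nwherever nb_model exceeds both references (treat-all 'nb_all' and")
print("treat-none 0) and the short-diameter rule, acting on the radiomic")
print("prediction spares more benign nodes per unnecessary treatment than")
print("any alternative strategy at that risk threshold.")
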