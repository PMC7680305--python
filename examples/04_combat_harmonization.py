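"""Remove scanner batch effects from a feature table with parametric ComBat.

Each scanner shifts and scales feature values (offset HU, gain).  ComBat
standardizes every feature, estimates per-batch location and scale, shrinks
them across features with an empirical-Bayes prior, and removes them.
"""

import numpy as np
import pandas as pd

from lnrad import combat_apply, combat_fit

rng = np.random.default_rng(5)
n = 150
batch = np.array(["scannerA"] * n + ["scannerB"] * n)
table = pd.DataFrame({
    "firstorder_Mean": np.r_[rng.normal(45, 8, n), rng.normal(45, 8, n) + 9.0],
    "glcm_Contrast": np.r_[rng.normal(5, 1, n), 1.6 * rng.normal(5, 1, n) - 3.0],
    "shape_MeshVolume": np.r_[rng.normal(150, 40, n), rng.normal(150, 40, n)],
})

def batch_means(t):
    return t.groupby(batch).mean().round(2)

print("per-batch feature means BEFORE harmonization:")
print(batch_means(table), "\n")

params = combat_fit(table, batch)
adjusted = combat_apply(table, batch, params)

print("per-batch feature means AFTER harmonization:")
print(batch_means(adjusted))
print("\nthe 9-HU scanner offset on firstorder_Mean and the gain on")
print("glcm_Contrast are gone; the batch-free shape_MeshVolume is untouched")
print("up to the shrinkage noise floor.")
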