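"""Generate a small synthetic CT lymph-node cohort and inspect its structure.

The phantom emulates the study population the analysis is designed for:
small contrast-enhanced soft-tissue lesions (~0.15 cm^3), ~74% node-level
metastasis prevalence, one in-house training scanner and several external
test scanners with additive/multiplicative batch effects, and a second
independent segmentation for a subset of training patients.
"""

import numpy as np

from lnrad import PhantomConfig, cohort_metadata, dice, generate_cohort

config = PhantomConfig(n_patients_train=12, n_patients_test=8,
                       rater2_n_patients=6, seed=7)
nodes = generate_cohort(config)
meta = cohort_metadata(nodes)

print(f"{len(nodes)} nodes from "
      f"{meta.patient_id.nunique()} patients ({(meta.cohort == 'train').sum()} train"
      f" / {(meta.cohort == 'test').sum()} test nodes)")
print("\nnode-level prevalence by cohort (fraction of metastatic nodes):")
print(meta.groupby("cohort").label.mean().round(3).to_string())
print("\nscanner batches:", dict(meta.batch.value_counts()))
print(f"mean lesion volume: {meta.volume_mm3.mean() / 1000:.3f} cm^3"
      f"  |  mean short diameter: {meta.short_diameter_mm.mean():.1f} mm")

pairs = [n for n in nodes if n.mask_rater2 is not None]
dices = [dice(n.mask_rater1, n.mask_rater2) for n in pairs]
print(f"\n{len(pairs)} nodes carry a second independent segmentation; "
      f"median Dice overlap {np.median(dices):.3f}")
print("(the rater-2 perturbation is calibrated so this sits near 0.89,")
print(" the agreement level typical of expert re-delineation of small nodes)")
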