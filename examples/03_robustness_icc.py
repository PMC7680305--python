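"""Quantify feature robustness to segmentation variability with ICC(3,1).

Features are extracted twice per node, once from each rater's mask; a
feature whose two-way mixed, single-measure, consistency ICC falls below
0.8 depends too much on who drew the contour and is excluded from modeling.
"""

from lnrad import PhantomConfig, extract_cohort_features, filter_features, generate_cohort

nodes = generate_cohort(PhantomConfig(
    n_patients_train=20, n_patients_test=2, rater2_n_patients=20, seed=11))
_, rater1, rater2, rater_dice = extract_cohort_features(nodes)

print(f"{len(rater1)} nodes with two independent segmentations "
      f"(median Dice {rater_dice.dice.median():.3f})")

report = filter_features(rater1, rater2, threshold=0.8)
print(f"retained {len(report.retained)} / {len(report.table)} features at ICC >= 0.8\n")
print("exclusion fraction by feature class:")
for cls in ("shape", "intensity", "texture", "lbp"):
    print(f"  {cls:10s} {report.exclusion_fraction(cls):.0%}")
print("\nshape features suffer most from boundary disagreement (volume and")
print("surface quantities move with every re-drawn contour), while the LBP")
print("maps, computed from the image itself, barely notice the mask change.")
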