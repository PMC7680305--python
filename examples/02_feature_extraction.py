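"""Extract the 156-feature radiomics panel from one lesion.

The panel is 18 first-order (intensity) + 10 shape + 74 texture (GLCM,
GLRLM, GLSZM, GLDM, NGTDM) + 54 statistics of the three 3D local-binary-
pattern maps (level-1 energy, level-2 energy, kurtosis).  Preprocessing is
1 mm isotropic B-spline resampling and fixed 5-HU bin-width discretization.
"""

import numpy as np

from lnrad import extract_panel, feature_class, make_lesion

rng = np.random.default_rng(3)
image, mask = make_lesion(volume_target_cm3=0.15, shape_eccentricity=0.2,
                          texture_amplitude=12.0, rng=rng)
print(f"lesion: {mask.n_voxels} voxels at {mask.spacing} mm spacing "
      f"({mask.volume_mm3 / 1000:.3f} cm^3)")

features = extract_panel(image, mask)
counts = {}
for name in features:
    counts[feature_class(name)] = counts.get(feature_class(name), 0) + 1
print(f"{len(features)} features extracted: {counts}")

show = ["firstorder_Mean", "firstorder_Entropy", "shape_Sphericity",
        "shape_SurfaceVolumeRatio", "glcm_Contrast", "ngtdm_Coarseness",
        "lbp-k_10Percentile", "lbp-k_InterquartileRange"]
print("\nselected values:")
for name in show:
    print(f"  {name:32s} {features[name]:10.4f}")
print("\nshape_SurfaceVolumeRatio (1/mm) grows as lesions get smaller or"
      "\nmore irregular; the two lbp-k statistics are the strongest single"
      "\npredictors of metastasis in the combined model.")
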