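"""First-order (intensity histogram) statistics of a VOI.

Eighteen statistics computed from the raw in-mask intensities; Entropy and
Uniformity use the fixed-bin-width discretized gray levels.  Statistics that
are undefined on a constant VOI (skewness, kurtosis) return 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = [
    "Mean",
    "Median",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Uniformity",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
]


def first_order_features(
    values: np.ndarray,
    bins: np.ndarray | None = None,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """The 18 first-order statistics of a set of in-mask intensities.

    Parameters
    ----------
    values : 1D array
        Raw intensities of the in-mask voxels.
    bins : 1D int array, optional
        Discretized gray level per voxel (1-based); required for Entropy and
        Uniformity.  If omitted, the raw values are binned at unit width.
    voxel_volume_mm3 : float
        Physical voxel volume; scales TotalEnergy.

    Notes
    -----
    Variance and skewness are population (biased) moments; Kurtosis is the
    plain (non-excess) fourth standardized moment, so a Gaussian gives 3.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty VOI")
    if bins is None:
        bins = (np.floor(x) - np.floor(x.min()) + 1).astype(np.int64)

    n = x.size
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    sd = np.sqrt(var)
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = 0.0
        kurt = 0.0

    counts = np.bincount(np.asarray(bins, dtype=np.int64))[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    return {
        "Mean": mean,
        "Median": float(p50),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": energy,
        "TotalEnergy": float(voxel_volume_mm3 * energy),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
    }
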