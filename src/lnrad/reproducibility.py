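"""Segmentation agreement and feature robustness.

Features whose value depends strongly on who drew the contour are excluded
before modeling: each node of the paired subset is segmented twice, features
are extracted from both masks, and any feature with a two-way mixed,
single-measure, consistency intraclass correlation — ICC(3,1) in the
Shrout-Fleiss numbering — below 0.8 is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import SegmentationMask
from .panel import feature_class

__all__ = ["dice", "icc31", "filter_features", "RobustnessReport"]


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two aligned masks.

    Two empty masks are defined to agree perfectly (returns 1.0).
    Raises ``ValueError`` on a grid mismatch.
    """
    if not a.same_grid(b):
        raise ValueError("masks are not on the same grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def icc31(ratings: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, single-measure, consistency.

    ``ratings`` is a (subjects x raters) matrix with no missing cells.
    From the two-way ANOVA decomposition with n subjects and k raters:

        ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k-1) * MS_error)

    Consistency ICC is blind to fixed rater offsets: adding a constant to
    one rater's column leaves it unchanged.  If both the between-subject and
    residual mean squares vanish (all values identical), the measurement
    carries no information and 0.0 is returned.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (>=2 subjects) x (>=2 raters) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        return 0.0
    return float((ms_rows - ms_err) / denom)


@dataclass
class RobustnessReport:
    """Per-feature ICC values, retention flags and per-class exclusion fractions."""

    table: pd.DataFrame            # columns: feature, class, icc, retained, degenerate
    threshold: float

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table.retained, "feature"].tolist()

    @property
    def excluded(self) -> list[str]:
        return self.table.loc[~self.table.retained, "feature"].tolist()

    def exclusion_fraction(self, cls: str) -> float:
        sub = self.table[self.table["class"] == cls]
        if len(sub) == 0:
            return float("nan")
        return float(1.0 - sub.retained.mean())


def filter_features(
    rater1: pd.DataFrame,
    rater2: pd.DataFrame,
    threshold: float = 0.8,
) -> RobustnessReport:
    """Exclude segmentation-sensitive features by ICC(3,1) < threshold.

    ``rater1`` and ``rater2`` hold the same nodes (rows, aligned) and the
    same feature columns, extracted from the two independent segmentations.
    A feature that is constant across all subjects for both raters carries
    no between-subject variance; it is flagged degenerate and excluded.
    """
    if list(rater1.columns) != list(rater2.columns):
        raise ValueError("rater tables must have identical feature columns")
    if len(rater1) != len(rater2):
        raise ValueError("rater tables must have the same rows")
    if len(rater1) < 2:
        raise ValueError("ICC needs at least 2 subjects")

    rows = []
    for col in rater1.columns:
        pair = np.column_stack([rater1[col].to_numpy(), rater2[col].to_numpy()])
        degenerate = bool(np.allclose(pair.std(axis=0), 0.0))
        icc = 0.0 if degenerate else icc31(pair)
        rows.append(
            {
                "feature": col,
                "class": feature_class(col),
                "icc": icc,
                "retained": (not degenerate) and icc >= threshold,
                "degenerate": degenerate,
            }
        )
    return RobustnessReport(table=pd.DataFrame(rows), threshold=threshold)
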