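"""The 156-feature extraction panel.

18 first-order (intensity) + 10 shape + 74 texture (23 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM) + 54 LBP-derived (18 first-order statistics of
each of the three LBP maps).  The exact list is pinned by a versioned JSON
manifest shipped with the package; the manifest is a reconstruction of a
panel of this size, with every choice (bin anchor, directions, LBP radius)
recorded alongside it.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np

from .firstorder import FIRSTORDER_NAMES, first_order_features
from .images import ImageVolume, SegmentationMask, discretize_fixed_bin_width, resample_isotropic
from .lbp3d import LBP_NAMES, lbp3d_maps, lbp_firstorder
from .shape import SHAPE_NAMES, shape_features
from .texture import TEXTURE_NAMES, texture_features, texture_matrices

__all__ = [
    "ExtractionConfig",
    "PANEL_NAMES",
    "feature_class",
    "extract_panel",
    "load_manifest",
]

PANEL_NAMES = (
    [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    + [f"shape_{n}" for n in SHAPE_NAMES]
    + TEXTURE_NAMES
    + LBP_NAMES
)
assert len(PANEL_NAMES) == 156 and len(set(PANEL_NAMES)) == 156


def feature_class(name: str) -> str:
    """Map a feature name to its class: intensity | shape | texture | lbp."""
    if name.startswith("firstorder_"):
        return "intensity"
    if name.startswith("shape_"):
        return "shape"
    if name.startswith("lbp-"):
        return "lbp"
    return "texture"


@dataclass
class ExtractionConfig:
    """Settings of the feature extractor.

    target_spacing : isotropic resampling spacing in mm (cubic B-spline).
    bin_width : fixed HU bin width for gray-level discretization.
    lbp_radius_mm : radius of the LBP sampling sphere.
    lbp_subdivisions : icosphere subdivision level (1 -> 42 samples).
    lbp_n_bins : number of equal-width bins for LBP-map entropy/uniformity.
    resample : set False when inputs are already on the target grid.
    """

    target_spacing: float = 1.0
    bin_width: float = 5.0
    lbp_radius_mm: float = 1.0
    lbp_subdivisions: int = 1
    lbp_n_bins: int = 32
    resample: bool = True


def _crop_to_mask(
    image: ImageVolume, mask: SegmentationMask, cfg: ExtractionConfig
) -> tuple[ImageVolume, SegmentationMask]:
    """Crop to the mask bounding box plus a margin.

    The margin exceeds the LBP sampling radius, so every in-mask voxel keeps
    its full real-image neighborhood and all features are unchanged.
    """
    idx = np.argwhere(mask.voxels)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    margin = np.maximum(
        2, np.ceil(cfg.lbp_radius_mm / np.asarray(image.spacing)).astype(int) + 2
    )
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, mask.voxels.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(o + a * s for o, a, s in zip(image.origin, lo, image.spacing))
    return (
        ImageVolume(image.voxels[sl], image.spacing, origin),
        SegmentationMask(mask.voxels[sl], mask.spacing, origin),
    )


def extract_panel(
    image: ImageVolume,
    mask: SegmentationMask,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Extract the full 156-feature panel from one image/mask pair.

    Deterministic given its inputs.  Returns an ordered mapping whose keys
    equal :data:`PANEL_NAMES`.
    """
    cfg = config or ExtractionConfig()
    if cfg.resample:
        image, mask = resample_isotropic(image, mask, cfg.target_spacing)
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    image, mask = _crop_to_mask(image, mask, cfg)

    voi = discretize_fixed_bin_width(image, mask, cfg.bin_width)
    values = image.voxels[mask.voxels]

    out: dict[str, float] = {}
    fo = first_order_features(values, bins=voi.bins, voxel_volume_mm3=image.voxel_volume_mm3)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    out.update({f"shape_{k}": v for k, v in shape_features(mask).items()})
    out.update(texture_features(texture_matrices(voi)))
    maps = lbp3d_maps(image, cfg.lbp_radius_mm, cfg.lbp_subdivisions)
    out.update(lbp_firstorder(maps, mask, cfg.lbp_n_bins))

    ordered = {name: float(out[name]) for name in PANEL_NAMES}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return ordered


def load_manifest() -> dict:
    """The versioned feature manifest shipped with the package."""
    with importlib.resources.files("lnrad").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)
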