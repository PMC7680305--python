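"""Three-dimensional local-binary-pattern filter maps.

For every voxel, intensities are sampled by trilinear interpolation at N
points on a sphere of given physical radius (an icosphere with 42 nearly
uniform directions by default).  The binary pattern ``b_i = 1 if sample_i >
center else 0`` is expanded on the real spherical-harmonic basis; the level-1
and level-2 maps are the energies of the degree-1 and degree-2 components,
which makes them approximately rotation-invariant.  The third map is the
excess kurtosis of the *raw* neighbor-minus-center differences (the
binarized samples would have trivial kurtosis); zero-variance neighborhoods
map to 0.

The filter is invariant to adding a global constant to the image by
construction.  Volume borders are handled with mirror padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import sph_harm_y

from .firstorder import FIRSTORDER_NAMES, first_order_features
from .images import ImageVolume, SegmentationMask

__all__ = ["LBPMaps", "lbp3d_maps", "lbp_firstorder", "LBP_NAMES"]

LBP_PREFIXES = ("lbp-m1", "lbp-m2", "lbp-k")
LBP_NAMES = [f"{pfx}_{name}" for pfx in LBP_PREFIXES for name in FIRSTORDER_NAMES]


@dataclass
class LBPMaps:
    """Level-1, level-2 and kurtosis LBP maps on the source grid."""

    m1: ImageVolume
    m2: ImageVolume
    k: ImageVolume
    radius_mm: float
    n_samples: int


def _icosphere_directions(subdivisions: int = 1) -> np.ndarray:
    """Nearly uniform unit directions (42 for one subdivision)."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(ico.vertices, dtype=np.float64)


def _real_sph_basis(dirs: np.ndarray, level: int) -> np.ndarray:
    """Real spherical harmonics Y_{level,m} evaluated at unit directions.

    Returns an array of shape (2*level+1, n_dirs).
    """
    x, y, z = dirs[:, 2], dirs[:, 1], dirs[:, 0]  # dirs stored (z, y, x)
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    rows = []
    for m in range(-level, level + 1):
        ylm = sph_harm_y(level, abs(m), theta, phi)
        if m == 0:
            rows.append(ylm.real)
        elif m > 0:
            rows.append(np.sqrt(2.0) * (-1.0) ** m * ylm.real)
        else:
            rows.append(np.sqrt(2.0) * (-1.0) ** m * ylm.imag)
    return np.asarray(rows)


def lbp3d_maps(
    image: ImageVolume,
    radius_mm: float = 1.0,
    subdivisions: int = 1,
) -> LBPMaps:
    """Compute the level-1, level-2 and kurtosis LBP maps of a volume.

    ``radius_mm`` must be at least half the smallest voxel edge.  The input
    is expected to be (approximately) isotropically resampled; the sphere is
    expressed in voxel units through the per-axis spacing, so mildly
    anisotropic grids are handled correctly.
    """
    spacing = np.asarray(image.spacing)
    if radius_mm < 0.5 * spacing.min():
        raise ValueError(
            f"radius {radius_mm} mm is smaller than half a voxel ({spacing.min()} mm)"
        )
    dirs = _icosphere_directions(subdivisions)
    n = len(dirs)
    offsets_vox = dirs * radius_mm / spacing  # (n, 3) in index units

    shape = image.voxels.shape
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0], dtype=np.float64),
        np.arange(shape[1], dtype=np.float64),
        np.arange(shape[2], dtype=np.float64),
        indexing="ij",
    )
    base = np.stack([zz.ravel(), yy.ravel(), xx.ravel()])

    diffs = np.empty((n, base.shape[1]))
    center = image.voxels.ravel()
    for i, off in enumerate(offsets_vox):
        coords = base + off[:, None]
        sampled = map_coordinates(image.voxels, coords, order=1, mode="reflect")
        diffs[i] = sampled - center

    # ties count as 0; the tolerance absorbs interpolation round-off, which
    # would otherwise flip patterns on exactly flat regions
    b = (diffs > 1e-6).astype(np.float64)

    def level_energy(level: int) -> np.ndarray:
        basis = _real_sph_basis(dirs, level)          # (2l+1, n)
        coeff = basis @ b * (4.0 * np.pi / n)         # quadrature on the icosphere
        return (coeff**2).sum(axis=0)

    m1 = level_energy(1).reshape(shape)
    m2 = level_energy(2).reshape(shape)

    mu = diffs.mean(axis=0)
    var = diffs.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m4 = ((diffs - mu) ** 4).mean(axis=0)
        kurt = np.where(var > 1e-12, m4 / np.where(var > 0, var**2, 1.0) - 3.0, 0.0)
    k = kurt.reshape(shape)

    make = lambda a: ImageVolume(a, image.spacing, image.origin)
    return LBPMaps(m1=make(m1), m2=make(m2), k=make(k), radius_mm=radius_mm, n_samples=n)


def lbp_firstorder(
    maps: LBPMaps, mask: SegmentationMask, n_bins: int = 32
) -> dict[str, float]:
    """The 18 first-order statistics of each LBP map inside the mask (54 values).

    Entropy/Uniformity use ``n_bins`` equal-width bins over the in-mask range
    of each map (the maps are not on the HU scale, so a fixed absolute bin
    width is not meaningful).
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    out: dict[str, float] = {}
    for pfx, vol in zip(LBP_PREFIXES, (maps.m1, maps.m2, maps.k)):
        if not mask.same_grid(vol):
            raise ValueError("mask and LBP map are not on the same grid")
        vals = vol.voxels[mask.voxels]
        rng = float(vals.max() - vals.min())
        if rng > 0:
            bins = np.minimum((vals - vals.min()) / (rng / n_bins), n_bins - 1).astype(int) + 1
        else:
            bins = np.ones(vals.size, dtype=int)
        feats = first_order_features(vals, bins=bins, voxel_volume_mm3=vol.voxel_volume_mm3
                                     if hasattr(vol, "voxel_volume_mm3") else 1.0)
        out.update({f"{pfx}_{k}": v for k, v in feats.items()})
    return out
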