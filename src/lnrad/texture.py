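"""Gray-level texture matrices and their features (IBSI-style definitions).

Five families are computed from the discretized VOI (1-based gray levels on
the voxel grid, 0 outside the mask):

* GLCM  — co-occurrence at distance 1 over the 13 unique 3D directions,
          symmetrized; features computed per direction, then averaged.
* GLRLM — run lengths over the same 13 directions, feature-level averaging.
* GLSZM — connected zones of equal gray level (26-connectivity).
* GLDM  — dependence counts over the 26-neighborhood (alpha = 0); the
          dependence size includes the center voxel, so it is >= 1.
* NGTDM — gray-tone difference against the mean of in-mask 26-neighbors.

Features undefined on degenerate (single-gray-level) VOIs return the
documented fallback: 0 for entropies/contrasts, 1 for GLCM Correlation and
MCC, and the 1e6 cap for NGTDM Coarseness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import DiscretizedVOI

__all__ = [
    "GrayLevelMatrices",
    "texture_matrices",
    "texture_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "TEXTURE_NAMES",
]

# one direction per antipodal pair of the 26-neighborhood
DIRECTIONS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

_EPS = np.spacing(1.0)


@dataclass
class GrayLevelMatrices:
    """Raw texture matrices of one VOI.

    glcm : (13, Ng, Ng) symmetric pair counts per direction
    glrlm : (13, Ng, Rmax) run counts per direction
    glszm : (Ng, Smax) zone counts
    gldm : (Ng, Dmax) dependence counts
    ngtdm : (Ng, 3) columns = n_i, p_i, s_i
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm: np.ndarray
    n_bins: int
    n_voxels: int


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _shift_slices(shape, d):
    """Slices (a, b) so that grid[a] and grid[b] are voxel pairs offset by d."""
    sa, sb = [], []
    for n, step in zip(shape, d):
        if step == 0:
            sa.append(slice(None))
            sb.append(slice(None))
        elif step > 0:
            sa.append(slice(0, n - step))
            sb.append(slice(step, n))
        else:
            sa.append(slice(-step, n))
            sb.append(slice(0, n + step))
    return tuple(sa), tuple(sb)


def _glcm(grid: np.ndarray, ng: int) -> np.ndarray:
    out = np.zeros((len(DIRECTIONS_13), ng, ng))
    for k, d in enumerate(DIRECTIONS_13):
        sa, sb = _shift_slices(grid.shape, d)
        a, b = grid[sa].ravel(), grid[sb].ravel()
        keep = (a > 0) & (b > 0)
        if keep.any():
            m = np.zeros((ng, ng))
            np.add.at(m, (a[keep] - 1, b[keep] - 1), 1)
            out[k] = m + m.T
    return out


def _glrlm(grid: np.ndarray, ng: int) -> np.ndarray:
    rmax = max(grid.shape)
    # diagonal runs can exceed the max edge length in voxel count? no:
    # a run along any direction visits at most max(shape) voxels
    out = np.zeros((len(DIRECTIONS_13), ng, rmax))
    shape = grid.shape
    for k, d in enumerate(DIRECTIONS_13):
        # run starts: in-mask voxels whose predecessor along d differs
        prev = np.zeros(shape, dtype=np.int64)
        sa, sb = _shift_slices(shape, d)
        prev[sb] = grid[sa]
        starts = np.argwhere((grid > 0) & (grid != prev))
        if len(starts) == 0:
            continue
        gray = grid[tuple(starts.T)]
        pos = starts.copy()
        length = np.ones(len(starts), dtype=np.int64)
        alive = np.ones(len(starts), dtype=bool)
        dvec = np.asarray(d)
        while alive.any():
            nxt = pos[alive] + dvec
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(ok.shape, dtype=bool)
            if ok.any():
                vals = grid[tuple(nxt[ok].T)]
                cont[ok] = vals == gray[alive][ok]
            idx = np.flatnonzero(alive)
            still = idx[cont]
            length[still] += 1
            pos[still] += dvec
            alive[idx[~cont]] = False
        m = np.zeros((ng, rmax))
        np.add.at(m, (gray - 1, length - 1), 1)
        out[k] = m
    return out


def _glszm(grid: np.ndarray, ng: int, n_voxels: int) -> np.ndarray:
    struct = np.ones((3, 3, 3), dtype=int)
    sizes_by_gray: list[tuple[int, int]] = []
    smax = 1
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(grid == g, structure=struct)
        if nlab == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        for c in counts:
            sizes_by_gray.append((g, int(c)))
            smax = max(smax, int(c))
    out = np.zeros((ng, smax))
    for g, s in sizes_by_gray:
        out[g - 1, s - 1] += 1
    return out


def _neighbor_offsets():
    return [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]


def _gldm(grid: np.ndarray, ng: int, alpha: float = 0.0) -> np.ndarray:
    inside = grid > 0
    dep = np.zeros(grid.shape, dtype=np.int64)
    for d in _neighbor_offsets():
        sa, sb = _shift_slices(grid.shape, d)
        ok = inside[sa] & inside[sb] & (np.abs(grid[sa] - grid[sb]) <= alpha)
        dep[sa] += ok
    dmax = int(dep[inside].max()) + 1  # +1: dependence size includes the center
    out = np.zeros((ng, dmax))
    np.add.at(out, (grid[inside] - 1, dep[inside]), 1)
    return out


def _ngtdm(grid: np.ndarray, ng: int) -> np.ndarray:
    inside = grid > 0
    nsum = np.zeros(grid.shape)
    ncnt = np.zeros(grid.shape, dtype=np.int64)
    for d in _neighbor_offsets():
        sa, sb = _shift_slices(grid.shape, d)
        ok = inside[sb]
        nsum[sa] += np.where(ok, grid[sb], 0)
        ncnt[sa] += ok
    valid = inside & (ncnt > 0)
    nvp = int(valid.sum())
    gray = grid[valid]
    diff = np.abs(gray - nsum[valid] / ncnt[valid])
    out = np.zeros((ng, 3))
    np.add.at(out[:, 0], gray - 1, 1)
    np.add.at(out[:, 2], gray - 1, diff)
    out[:, 1] = out[:, 0] / max(nvp, 1)
    return out


def texture_matrices(voi: DiscretizedVOI) -> GrayLevelMatrices:
    """All five texture matrices of a discretized VOI."""
    grid = voi.grid
    ng = voi.n_bins
    n_vox = int((grid > 0).sum())
    return GrayLevelMatrices(
        glcm=_glcm(grid, ng),
        glrlm=_glrlm(grid, ng),
        glszm=_glszm(grid, ng, n_vox),
        gldm=_gldm(grid, ng),
        ngtdm=_ngtdm(grid, ng),
        n_bins=ng,
        n_voxels=n_vox,
    )


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------

GLCM_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
]


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())          # symmetric: mu_x == mu_y
    sigma2 = float((px * (i - mu) ** 2).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    da = float((k_diff * p_diff).sum())
    hxy = ent(p.ravel())
    hx = ent(px)
    outer = np.outer(px, px)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    nzo = outer > 0
    hxy2 = float(-(outer[nzo] * np.log2(outer[nzo])).sum())

    if sigma2 > 0:
        corr = float(((p * (ii - mu) * (jj - mu)).sum()) / sigma2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0.0)))) if hxy2 >= hxy else 0.0

    # MCC: second largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    if ng > 1 and (px > 0).sum() > 1:
        keep = px > 0
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if len(ev) > 1 else 1.0
    else:
        mcc = 1.0

    kd1 = k_diff[1:]
    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + k_diff**2 / ng**2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / kd1**2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": sigma2,
    }


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Per-direction GLCM features averaged over directions with pairs."""
    per_dir = []
    for k in range(glcm.shape[0]):
        total = glcm[k].sum()
        if total > 0:
            per_dir.append(_glcm_features_single(glcm[k] / total))
    if not per_dir:
        return {name: 0.0 for name in GLCM_NAMES}
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}


GLRLM_NAMES = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _size_gray_features(m: np.ndarray, n_voxels: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared formulas of the GLRLM/GLSZM families.

    ``m[i-1, r-1]`` counts runs/zones of gray level i and size r; ``prefix``
    maps the generic names (Short/Long/Size...) onto the family's naming.
    """
    ns = m.sum()
    if ns == 0:
        return {v: 0.0 for v in prefix.values()}
    i = np.arange(1, m.shape[0] + 1, dtype=np.float64)
    r = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    mi = m.sum(axis=1)
    mr = m.sum(axis=0)
    p = m / ns
    mu_i = float((mi / ns * i).sum())
    mu_r = float((mr / ns * r).sum())
    pn = p[p > 0]
    out = {
        "sre": float((mr / r**2).sum() / ns),
        "lre": float((mr * r**2).sum() / ns),
        "gln": float((mi**2).sum() / ns),
        "glnn": float((mi**2).sum() / ns**2),
        "rln": float((mr**2).sum() / ns),
        "rlnn": float((mr**2).sum() / ns**2),
        "rp": float(ns / n_voxels),
        "glv": float((p * ((i - mu_i) ** 2)[:, None]).sum()),
        "rv": float((p * ((r - mu_r) ** 2)[None, :]).sum()),
        "rent": float(-(pn * np.log2(pn)).sum()),
        "lgl": float(((mi / i**2).sum()) / ns),
        "hgl": float(((mi * i**2).sum()) / ns),
        "srlgl": float((m / np.outer(i**2, r**2)).sum() / ns),
        "srhgl": float((m * np.outer(i**2, 1 / r**2)).sum() / ns),
        "lrlgl": float((m * np.outer(1 / i**2, r**2)).sum() / ns),
        "lrhgl": float((m * np.outer(i**2, r**2)).sum() / ns),
    }
    return {v: out[k] for k, v in prefix.items()}


_GLRLM_MAP = {
    "sre": "ShortRunEmphasis",
    "lre": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "RunLengthNonUniformity",
    "rlnn": "RunLengthNonUniformityNormalized",
    "rp": "RunPercentage",
    "glv": "GrayLevelVariance",
    "rv": "RunVariance",
    "rent": "RunEntropy",
    "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "srlgl": "ShortRunLowGrayLevelEmphasis",
    "srhgl": "ShortRunHighGrayLevelEmphasis",
    "lrlgl": "LongRunLowGrayLevelEmphasis",
    "lrhgl": "LongRunHighGrayLevelEmphasis",
}


def glrlm_features(glrlm: np.ndarray, n_voxels: int) -> dict[str, float]:
    per_dir = [
        _size_gray_features(glrlm[k], n_voxels, _GLRLM_MAP)
        for k in range(glrlm.shape[0])
        if glrlm[k].sum() > 0
    ]
    if not per_dir:
        return {name: 0.0 for name in GLRLM_NAMES}
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


GLSZM_NAMES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_GLSZM_MAP = {
    "sre": "SmallAreaEmphasis",
    "lre": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "SizeZoneNonUniformity",
    "rlnn": "SizeZoneNonUniformityNormalized",
    "rp": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "rv": "ZoneVariance",
    "rent": "ZoneEntropy",
    "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "srlgl": "SmallAreaLowGrayLevelEmphasis",
    "srhgl": "SmallAreaHighGrayLevelEmphasis",
    "lrlgl": "LargeAreaLowGrayLevelEmphasis",
    "lrhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glszm_features(glszm: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_gray_features(glszm, n_voxels, _GLSZM_MAP)


GLDM_NAMES = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

_GLDM_MAP = {
    "sre": "SmallDependenceEmphasis",
    "lre": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity",
    "rln": "DependenceNonUniformity",
    "rlnn": "DependenceNonUniformityNormalized",
    "glv": "GrayLevelVariance",
    "rv": "DependenceVariance",
    "rent": "DependenceEntropy",
    "lgl": "LowGrayLevelEmphasis",
    "hgl": "HighGrayLevelEmphasis",
    "srlgl": "SmallDependenceLowGrayLevelEmphasis",
    "srhgl": "SmallDependenceHighGrayLevelEmphasis",
    "lrlgl": "LargeDependenceLowGrayLevelEmphasis",
    "lrhgl": "LargeDependenceHighGrayLevelEmphasis",
}


def gldm_features(gldm: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_gray_features(gldm, n_voxels, _GLDM_MAP)


NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def ngtdm_features(ngtdm: np.ndarray) -> dict[str, float]:
    n_i = ngtdm[:, 0]
    p_i = ngtdm[:, 1]
    s_i = ngtdm[:, 2]
    nvp = n_i.sum()
    if nvp == 0:
        return {name: 0.0 for name in NGTDM_NAMES}
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)
    act = p_i > 0
    ngp = int(act.sum())
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        pi_a, ii_a, si_a = p_i[act], i[act], s_i[act]
        dif2 = (ii_a[:, None] - ii_a[None, :]) ** 2
        contrast = float(
            (pi_a[:, None] * pi_a[None, :] * dif2).sum()
            / (ngp * (ngp - 1))
            * s_i.sum()
            / nvp
        )
        denom = float(np.abs(ii_a[:, None] * pi_a[:, None] - ii_a[None, :] * pi_a[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        complexity = float(
            (
                np.abs(ii_a[:, None] - ii_a[None, :])
                * (pi_a[:, None] * si_a[:, None] + pi_a[None, :] * si_a[None, :])
                / (pi_a[:, None] + pi_a[None, :])
            ).sum()
            / nvp
        )
        ssum = s_i.sum()
        strength = (
            float(((pi_a[:, None] + pi_a[None, :]) * dif2).sum()) / ssum if ssum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


TEXTURE_NAMES = (
    [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_NAMES]
    + [f"glszm_{n}" for n in GLSZM_NAMES]
    + [f"gldm_{n}" for n in GLDM_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_NAMES]
)


def texture_features(matrices: GrayLevelMatrices) -> dict[str, float]:
    """All 74 texture features, keys prefixed by family."""
    out: dict[str, float] = {}
    out.update({f"glcm_{k}": v for k, v in glcm_features(matrices.glcm).items()})
    out.update(
        {f"glrlm_{k}": v for k, v in glrlm_features(matrices.glrlm, matrices.n_voxels).items()}
    )
    out.update(
        {f"glszm_{k}": v for k, v in glszm_features(matrices.glszm, matrices.n_voxels).items()}
    )
    out.update(
        {f"gldm_{k}": v for k, v in gldm_features(matrices.gldm, matrices.n_voxels).items()}
    )
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(matrices.ngtdm).items()})
    return out
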