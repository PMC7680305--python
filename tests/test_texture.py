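"""Texture matrices and features against brute-force enumeration oracles."""

import numpy as np
import pytest

from lnrad.texture import (
    DIRECTIONS_13,
    GrayLevelMatrices,
    _glcm,
    _gldm,
    _glrlm,
    _glszm,
    _ngtdm,
    glcm_features,
    texture_features,
    texture_matrices,
)

import oracles
from conftest import grid_voi, random_voi


@pytest.fixture(params=range(6))
def voi(request):
    rng = np.random.default_rng(100 + request.param)
    shapes = [(3, 3, 3), (4, 4, 4), (5, 5, 5), (2, 5, 4), (5, 2, 3), (4, 3, 5)]
    return random_voi(rng, shape=shapes[request.param], n_levels=4)


class TestMatricesAgainstOracles:
    def test_glcm_equals_pair_enumeration(self, voi):
        ng = voi.n_bins
        mats = _glcm(voi.grid, ng)
        for k, d in enumerate(DIRECTIONS_13):
            expected = np.zeros((ng, ng))
            for (a, b), c in oracles.glcm_pairs(voi.grid, d).items():
                expected[a - 1, b - 1] = c
            np.testing.assert_array_equal(mats[k], expected)

    def test_glrlm_equals_run_enumeration(self, voi):
        mats = _glrlm(voi.grid, voi.n_bins)
        for k, d in enumerate(DIRECTIONS_13):
            runs = oracles.glrlm_runs(voi.grid, d)
            expected = np.zeros_like(mats[k])
            for (g, length), c in runs.items():
                expected[g - 1, length - 1] = c
            np.testing.assert_array_equal(mats[k], expected)

    def test_glszm_equals_flood_fill(self, voi):
        n_vox = int((voi.grid > 0).sum())
        m = _glszm(voi.grid, voi.n_bins, n_vox)
        zones = oracles.glszm_zones(voi.grid)
        expected = np.zeros_like(m)
        for (g, size), c in zones.items():
            expected[g - 1, size - 1] = c
        np.testing.assert_array_equal(m, expected)

    def test_gldm_equals_neighbor_counting(self, voi):
        m = _gldm(voi.grid, voi.n_bins)
        expected = np.zeros_like(m)
        for (g, dep), c in oracles.gldm_counts(voi.grid).items():
            expected[g - 1, dep - 1] = c
        np.testing.assert_array_equal(m, expected)

    def test_ngtdm_equals_neighborhood_means(self, voi):
        m = _ngtdm(voi.grid, voi.n_bins)
        table = oracles.ngtdm_table(voi.grid)
        nvp = sum(n for n, _ in table.values())
        for g in range(1, voi.n_bins + 1):
            n_i, s_i = table.get(g, (0, 0.0))
            assert m[g - 1, 0] == n_i
            assert m[g - 1, 1] == pytest.approx(n_i / nvp)
            assert m[g - 1, 2] == pytest.approx(s_i, abs=1e-10)


class TestFeatureFormulas:
    def test_toy_glcm_counts_and_normalization(self):
        grid = np.array([[[1, 2], [2, 1]]]).reshape(2, 2, 1)
        voi = grid_voi(grid)
        mats = _glcm(voi.grid, 2)
        kx = DIRECTIONS_13.index((0, 0, 1))  # not present in this 2x2x1 layout
        ky = DIRECTIONS_13.index((0, 1, 0))
        m = mats[DIRECTIONS_13.index((1, 0, 0))]  # pairs along the first axis
        assert m[0, 1] == 2 and m[1, 0] == 2 and m[0, 0] == 0 and m[1, 1] == 0
        p = m / m.sum()
        assert p[0, 1] == pytest.approx(0.5) and p[1, 0] == pytest.approx(0.5)
        assert mats[kx].sum() == 0  # single voxel along x: no pairs
        assert mats[ky].sum() == 4  # (1,2) and (2,1) columns, symmetrized

    def test_glcm_contrast_equals_direct_summation(self, voi):
        mats = _glcm(voi.grid, voi.n_bins)
        feats = glcm_features(mats)
        vals = []
        for k in range(len(DIRECTIONS_13)):
            tot = mats[k].sum()
            if tot == 0:
                continue
            p = mats[k] / tot
            vals.append(
                sum(
                    p[i, j] * (i - j) ** 2
                    for i in range(voi.n_bins)
                    for j in range(voi.n_bins)
                )
            )
        assert feats["Contrast"] == pytest.approx(np.mean(vals), rel=1e-10)

    def test_single_run_long_run_emphasis_hand_count(self):
        # one run of length 4 at level 2 plus an isolated level-1 voxel, x-axis
        grid = np.zeros((1, 1, 6), dtype=int)
        grid[0, 0, :4] = 2
        grid[0, 0, 5] = 1
        voi = grid_voi(grid)
        m = _glrlm(voi.grid, 2)[DIRECTIONS_13.index((0, 0, 1))]
        # two runs: (level 2, len 4) and (level 1, len 1)
        assert m[1, 3] == 1 and m[0, 0] == 1 and m.sum() == 2
        lre = (1 * 1**2 + 1 * 4**2) / 2
        sre = (1 / 1**2 + 1 / 4**2) / 2
        assert lre == 8.5 and sre == pytest.approx(0.53125)

    def test_normalized_matrices_sum_to_one(self, voi):
        mats = texture_matrices(voi)
        for k in range(mats.glcm.shape[0]):
            tot = mats.glcm[k].sum()
            if tot > 0:
                assert (mats.glcm[k] / tot).sum() == pytest.approx(1.0)
        assert (mats.glszm / mats.glszm.sum()).sum() == pytest.approx(1.0)
        assert (mats.gldm / mats.gldm.sum()).sum() == pytest.approx(1.0)
        assert mats.gldm.sum() == mats.n_voxels  # one dependence entry per voxel

    def test_constant_voi_degenerate_values(self):
        grid = np.ones((3, 3, 3), dtype=int)
        feats = texture_features(texture_matrices(grid_voi(grid)))
        assert feats["glcm_Contrast"] == 0.0
        assert feats["glcm_Correlation"] == 1.0
        assert feats["glcm_JointEntropy"] == 0.0
        assert feats["ngtdm_Coarseness"] == 1e6  # zero tone difference: capped
        assert feats["glrlm_GrayLevelVariance"] == 0.0

    def test_all_features_finite(self, voi):
        feats = texture_features(texture_matrices(voi))
        assert len(feats) == 74
        assert all(np.isfinite(v) for v in feats.values())


class TestInvariances:
    def test_axis_rotation_preserves_direction_averaged_features(self, rng):
        """A 90-degree grid rotation permutes the 13 directions, leaving
        direction-averaged features unchanged."""
        grid = rng.integers(1, 5, size=(6, 6, 6))
        rot = np.rot90(grid, k=1, axes=(1, 2)).copy()
        f1 = texture_features(texture_matrices(grid_voi(grid)))
        f2 = texture_features(texture_matrices(grid_voi(rot)))
        for name, v in f1.items():
            assert f2[name] == pytest.approx(v, rel=1e-9), name
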