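"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (explicit loops,
direct enumeration) and stays independent of the package code paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBORS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def glcm_pairs(grid: np.ndarray, direction) -> dict[tuple[int, int], int]:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    counts: dict[tuple[int, int], int] = {}
    nz, ny, nx = grid.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = grid[z, y, x]
                if a == 0:
                    continue
                z2, y2, x2 = z + direction[0], y + direction[1], x + direction[2]
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = grid[z2, y2, x2]
                if b == 0:
                    continue
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def glrlm_runs(grid: np.ndarray, direction) -> dict[tuple[int, int], int]:
    """Run counts (gray, length) by walking every maximal run."""
    counts: dict[tuple[int, int], int] = {}
    nz, ny, nx = grid.shape
    d = direction
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                g = grid[z, y, x]
                if g == 0:
                    continue
                pz, py, px = z - d[0], y - d[1], x - d[2]
                if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx and grid[pz, py, px] == g:
                    continue  # not a run start
                length = 1
                cz, cy, cx = z + d[0], y + d[1], x + d[2]
                while 0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx and grid[cz, cy, cx] == g:
                    length += 1
                    cz, cy, cx = cz + d[0], cy + d[1], cx + d[2]
                counts[(g, length)] = counts.get((g, length), 0) + 1
    return counts


def glszm_zones(grid: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts (gray, size) by BFS flood fill with 26-connectivity."""
    seen = np.zeros(grid.shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    nz, ny, nx = grid.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                g = grid[z, y, x]
                if g == 0 or seen[z, y, x]:
                    continue
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in NEIGHBORS_26:
                        tz, ty, tx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx
                            and not seen[tz, ty, tx] and grid[tz, ty, tx] == g
                        ):
                            seen[tz, ty, tx] = True
                            stack.append((tz, ty, tx))
                counts[(g, size)] = counts.get((g, size), 0) + 1
    return counts


def gldm_counts(grid: np.ndarray, alpha: float = 0.0) -> dict[tuple[int, int], int]:
    """Dependence counts (gray, 1 + #dependent neighbors) per voxel."""
    counts: dict[tuple[int, int], int] = {}
    nz, ny, nx = grid.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                g = grid[z, y, x]
                if g == 0:
                    continue
                dep = 0
                for dz, dy, dx in NEIGHBORS_26:
                    tz, ty, tx = z + dz, y + dy, x + dx
                    if (
                        0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx
                        and grid[tz, ty, tx] != 0
                        and abs(int(grid[tz, ty, tx]) - int(g)) <= alpha
                    ):
                        dep += 1
                key = (g, dep + 1)
                counts[key] = counts.get(key, 0) + 1
    return counts


def ngtdm_table(grid: np.ndarray) -> dict[int, tuple[int, float]]:
    """Per gray level: (count n_i, summed |i - mean of in-mask neighbors| s_i)."""
    table: dict[int, tuple[int, float]] = {}
    nz, ny, nx = grid.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                g = grid[z, y, x]
                if g == 0:
                    continue
                vals = []
                for dz, dy, dx in NEIGHBORS_26:
                    tz, ty, tx = z + dz, y + dy, x + dx
                    if 0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx and grid[tz, ty, tx] != 0:
                        vals.append(grid[tz, ty, tx])
                if not vals:
                    continue
                n, s = table.get(g, (0, 0.0))
                table[g] = (n + 1, s + abs(g - float(np.mean(vals))))
    return table


def icc31_anova(x: np.ndarray) -> float:
    """ICC(3,1) by literal ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def auc_pair_counting(scores, y) -> float:
    """AUC by exhaustive concordant-pair counting, ties count 1/2."""
    s = np.asarray(scores, float)
    yv = np.asarray(y)
    pos = s[yv == 1]
    neg = s[yv == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def maxstat_exhaustive(scores, y, min_prop=0.1, max_prop=0.9):
    """Best split by evaluating the standardized rank statistic at every one."""
    import scipy.stats as st

    s = np.asarray(scores, float)
    yv = np.asarray(y, float)
    n = len(s)
    a = st.rankdata(yv)
    abar, avar = a.mean(), a.var(ddof=1)
    uniq = np.sort(np.unique(s))
    best, best_stat = None, -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2
        left = s <= cut
        n1 = left.sum()
        if not (min_prop <= n1 / n <= max_prop):
            continue
        var = n1 * (n - n1) * avar / n
        if var <= 0:
            continue
        stat = abs(a[left].sum() - n1 * abar) / np.sqrt(var)
        if stat > best_stat:
            best, best_stat = cut, stat
    return best, best_stat


def wilcoxon_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    import scipy.stats as st

    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled)
    na = len(a)
    observed = ranks[:na].sum()
    mean = ranks.mean() * na
    stats = [
        ranks[list(comb)].sum()
        for comb in itertools.combinations(range(len(pooled)), na)
    ]
    obs_dev = abs(observed - mean)
    extreme = sum(1 for t in stats if abs(t - mean) >= obs_dev - 1e-12)
    return extreme / len(stats)
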