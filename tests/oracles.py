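"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal enumeration straight from the
defining formulas — double loops over pixel pairs, explicit run
scanning, closed-form OLS — deliberately sharing no code with the
package so the two routes can disagree.
"""
from __future__ import annotations

import math

import numpy as np

# the 4 main directions and their opposites: symmetrized pair counting
_PAIR_OFFSETS = [(0, 1), (0, -1), (-1, 1), (1, -1), (-1, 0), (1, 0), (-1, -1), (1, 1)]


def glcm_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix by looping over all pairs."""
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in _PAIR_OFFSETS:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    counts[levels[r, c], levels[r2, c2]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def glcm_features_literal(p: np.ndarray) -> dict:
    """The nine co-occurrence features by explicit summation, levels 1..G."""
    g = p.shape[0]
    energy = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    entropy = -sum(
        p[i, j] * math.log2(p[i, j]) for i in range(g) for j in range(g) if p[i, j] > 0
    )
    contrast = sum(((i + 1) - (j + 1)) ** 2 * p[i, j] for i in range(g) for j in range(g))
    homogeneity = sum(p[i, j] / (1 + abs(i - j)) for i in range(g) for j in range(g))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    mu_x = sum((i + 1) * p[i, j] for i in range(g) for j in range(g))
    mu_y = sum((j + 1) * p[i, j] for i in range(g) for j in range(g))
    sx = math.sqrt(sum(((i + 1) - mu_x) ** 2 * p[i, j] for i in range(g) for j in range(g)))
    sy = math.sqrt(sum(((j + 1) - mu_y) ** 2 * p[i, j] for i in range(g) for j in range(g)))
    if sx * sy > 0:
        corr = sum(
            ((i + 1) - mu_x) * ((j + 1) - mu_y) * p[i, j] for i in range(g) for j in range(g)
        ) / (sx * sy)
    else:
        corr = 0.0
    p_sum = {k: 0.0 for k in range(2, 2 * g + 1)}
    p_diff = {k: 0.0 for k in range(0, g)}
    for i in range(g):
        for j in range(g):
            p_sum[(i + 1) + (j + 1)] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    sum_average = sum(k * v for k, v in p_sum.items())
    sum_variance = sum((k - sum_average) ** 2 * v for k, v in p_sum.items())
    mu_d = sum(k * v for k, v in p_diff.items())
    difference_variance = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    return {
        "energy": energy,
        "entropy": entropy,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": corr,
        "inv_diff_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "difference_variance": difference_variance,
    }


def rlm_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Run-length matrix over the four directions by explicit line scans."""
    h, w = levels.shape
    lmax = max(h, w)
    r = np.zeros((n_levels, lmax), dtype=int)
    n_runs = 0

    def scan(sequence):
        nonlocal n_runs
        run = []
        for cell in sequence + [None]:
            val = levels[cell] if (cell is not None and mask[cell]) else None
            if run and (val is None or val != run[-1][1]):
                r[run[0][1], len(run) - 1] += 1
                n_runs += 1
                run = []
            if val is not None:
                run.append((cell, val))

    for row in range(h):  # 0 deg
        scan([(row, c) for c in range(w)])
    for col in range(w):  # 90 deg
        scan([(rr, col) for rr in range(h)])
    for s in range(h + w - 1):  # 45 deg anti-diagonals
        scan([(rr, s - rr) for rr in range(h) if 0 <= s - rr < w])
    for d in range(-(h - 1), w):  # 135 deg diagonals
        scan([(rr, rr + d) for rr in range(h) if 0 <= rr + d < w])
    return r, n_runs, 4 * int(mask.sum())


def rlm_features_literal(r: np.ndarray, n_runs: int, pixel_basis: int) -> dict:
    g, lmax = r.shape
    feats = {k: 0.0 for k in
             ("sre", "lre", "gln", "rln", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")}
    for i0 in range(g):
        i = i0 + 1
        for j0 in range(lmax):
            j = j0 + 1
            v = float(r[i0, j0])
            feats["sre"] += v / j ** 2
            feats["lre"] += v * j ** 2
            feats["lgre"] += v / i ** 2
            feats["hgre"] += v * i ** 2
            feats["srlge"] += v / (i ** 2 * j ** 2)
            feats["srhge"] += v * i ** 2 / j ** 2
            feats["lrlge"] += v * j ** 2 / i ** 2
            feats["lrhge"] += v * i ** 2 * j ** 2
    feats["gln"] = float(sum(r[i0, :].sum() ** 2 for i0 in range(g)))
    feats["rln"] = float(sum(r[:, j0].sum() ** 2 for j0 in range(lmax)))
    out = {k: v / n_runs for k, v in feats.items()}
    out["rp"] = n_runs / pixel_basis
    return out


def ols_slope(x, y) -> float:
    """Closed-form least-squares slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())


def mann_whitney_auc(pos, neg) -> float:
    """AUC as explicit pair counting with half credit for ties."""
    u = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u / (len(pos) * len(neg))


def rank_sum(x, y) -> float:
    """Rank-sum of x in the pooled sample with midranks for ties."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + 1 + j) / 2.0  # midrank
        i = j
    return float(ranks[: len(x)].sum())
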