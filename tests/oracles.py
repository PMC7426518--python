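"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over pixels and
straight transcriptions of the defining formulas, with no shared code
with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(levels, mask, offset, n_levels):
    """Symmetric co-occurrence counts by exhaustive pixel enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    dr, dc = offset
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c], levels[r2, c2]
                counts[i, j] += 1
                counts[j, i] += 1
    return counts


def brute_runs(levels, mask, angle):
    """All maximal constant-level runs along one angle as (level, length)."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    step = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[angle]
    dr, dc = step
    # starting pixels: those with no in-grid predecessor along the step
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs = []
    for r, c in starts:
        cur_level, cur_len = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                lvl = levels[r, c]
                if lvl == cur_level:
                    cur_len += 1
                else:
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
                    cur_level, cur_len = lvl, 1
            else:
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = None, 0
            r, c = r + dr, c + dc
        if cur_level is not None:
            runs.append((cur_level, cur_len))
    return runs


def glcm_features_from_counts(counts, base=2.0):
    """CON/ENE/ENT/INC straight from the defining sums."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    p = counts / total
    n = p.shape[0]
    con = sum(
        (i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)
    )
    ene = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    lg = lambda x: math.log(x, base)
    ent = -sum(
        p[i, j] * lg(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
    )
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -sum(v * lg(v) for v in px if v > 0)
    hy = -sum(v * lg(v) for v in py if v > 0)
    hxy1 = -sum(
        p[i, j] * lg(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0
    )
    denom = max(hx, hy)
    inc = (ent - hxy1) / denom if denom > 0 else 0.0
    return {"CON": con, "ENE": ene, "ENT": ent, "INC": inc}


def grlm_features_from_runs(runs):
    """LRE/RLN/LGLRE/SRLGLE from a run list via the Galloway formulas."""
    nr = len(runs)
    lre = sum(length**2 for _, length in runs) / nr
    by_length: dict[int, int] = {}
    for _, length in runs:
        by_length[length] = by_length.get(length, 0) + 1
    rln = sum(v**2 for v in by_length.values()) / nr
    lglre = sum(1.0 / (lvl + 1) ** 2 for lvl, _ in runs) / nr
    srlgle = sum(1.0 / ((lvl + 1) ** 2 * length**2) for lvl, length in runs) / nr
    return {"LRE": lre, "RLN": rln, "LGLRE": lglre, "SRLGLE": srlgle}


def histogram_features_from_levels(x):
    """Population-moment skewness and non-excess kurtosis."""
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    return {"SKE": m3 / m2**1.5, "KUR": m4 / m2**2}


def auc_pair_fraction(scores, labels):
    """AUC as the exhaustive concordant-pair fraction (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def mannwhitney_exact_p(g0, g1):
    """Two-sided exact Mann-Whitney p by full permutation enumeration."""
    from itertools import combinations

    pooled = list(g0) + list(g1)
    n0 = len(g0)

    def u_stat(a, b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )

    mean_u = n0 * len(g1) / 2.0
    obs = abs(u_stat(g0, g1) - mean_u)
    idx = range(len(pooled))
    hits = total = 0
    for comb in combinations(idx, n0):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in idx if i not in comb]
        if abs(u_stat(a, b) - mean_u) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
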