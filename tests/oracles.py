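"""Independent brute-force oracles used to verify texture features.

These are deliberately naive, loop-based implementations, written straight
from the textbook definitions and sharing no code with the package.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def brute_glcm(levels, mask, offset, ng):
    """Symmetric co-occurrence probabilities by explicit pair enumeration."""
    dy, dx = offset
    h, w = levels.shape
    counts = Counter()
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                counts[(levels[y, x], levels[y2, x2])] += 1
                counts[(levels[y2, x2], levels[y, x])] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    p = np.zeros((ng, ng))
    for (i, j), c in counts.items():
        p[i, j] = c / total
    return p


def brute_glcm_features(p):
    """Haralick statistics with explicit loops; levels indexed 1..Ng."""
    ng = p.shape[0]

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))

    asm = contrast = idm = entropy = sumofsqs = corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            asm += v * v
            contrast += (i - j) ** 2 * v
            idm += v / (1 + (i - j) ** 2)
            entropy -= xlogx(v)
            sumofsqs += (i + 1 - mu) ** 2 * v
            corr_num += (i + 1) * (j + 1) * v
    correlation = (corr_num - mu * mu) / var if var > 0 else 0.0

    psum = [0.0] * (2 * ng + 1)  # index by i+j in 2..2Ng (1-based levels)
    pdiff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    sum_avg = sum(k * psum[k] for k in range(2, 2 * ng + 1))
    sum_var = sum((k - sum_avg) ** 2 * psum[k] for k in range(2, 2 * ng + 1))
    sum_ent = -sum(xlogx(psum[k]) for k in range(2, 2 * ng + 1))
    mu_d = sum(k * pdiff[k] for k in range(ng))
    dif_var = sum((k - mu_d) ** 2 * pdiff[k] for k in range(ng))
    dif_ent = -sum(xlogx(pdiff[k]) for k in range(ng))

    return {
        "AngScMom": asm,
        "Contrast": contrast,
        "Correlat": correlation,
        "SumOfSqs": sumofsqs,
        "InvDfMom": idm,
        "SumAverg": sum_avg,
        "SumVarnc": sum_var,
        "SumEntrp": sum_ent,
        "Entropy": entropy,
        "DifVarnc": dif_var,
        "DifEntrp": dif_ent,
    }


def _lines(h, w, angle):
    """Pixel index sequences of each scanline, by direction."""
    if angle == 0:
        return [[(y, x) for x in range(w)] for y in range(h)]
    if angle == 90:
        return [[(y, x) for y in range(h)] for x in range(w)]
    if angle == 135:  # main diagonals: step (+1, +1)
        starts = [(y, 0) for y in range(h - 1, 0, -1)] + [(0, x) for x in range(w)]
        out = []
        for y0, x0 in starts:
            line, y, x = [], y0, x0
            while y < h and x < w:
                line.append((y, x))
                y, x = y + 1, x + 1
            out.append(line)
        return out
    if angle == 45:  # anti-diagonals: step (-1, +1)
        starts = [(y, 0) for y in range(h)] + [(h - 1, x) for x in range(1, w)]
        out = []
        for y0, x0 in starts:
            line, y, x = [], y0, x0
            while y >= 0 and x < w:
                line.append((y, x))
                y, x = y - 1, x + 1
            out.append(line)
        return out
    raise ValueError(angle)


def brute_runs(levels, mask, angle):
    """All maximal in-mask constant-level runs: list of (level, length)."""
    runs = []
    for line in _lines(*levels.shape, angle):
        cur_lvl, cur_len = None, 0
        for y, x in line:
            if mask[y, x] and levels[y, x] == cur_lvl:
                cur_len += 1
            else:
                if cur_lvl is not None and cur_len:
                    runs.append((cur_lvl, cur_len))
                if mask[y, x]:
                    cur_lvl, cur_len = levels[y, x], 1
                else:
                    cur_lvl, cur_len = None, 0
        if cur_lvl is not None and cur_len:
            runs.append((cur_lvl, cur_len))
    return runs


def brute_glrlm_features(levels, mask, angle):
    runs = brute_runs(levels, mask, angle)
    n = len(runs)
    if n == 0:
        return None
    n_px = sum(l for _, l in runs)
    lvl_counts = Counter(g for g, _ in runs)
    len_counts = Counter(l for _, l in runs)
    return {
        "ShrtREmp": sum(c / l**2 for l, c in len_counts.items()) / n,
        "LngREmph": sum(c * l**2 for l, c in len_counts.items()) / n,
        "GLevNonU": sum(c**2 for c in lvl_counts.values()) / n,
        "RLNonUni": sum(c**2 for c in len_counts.values()) / n,
        "Fraction": n / n_px,
    }


def brute_median_3x3(img):
    """Median filter with radius 1 by explicit window collection (reflect)."""
    h, w = img.shape
    pad = np.pad(img, 1, mode="symmetric")  # scipy's 'reflect' convention
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            out[y, x] = np.median(pad[y : y + 3, x : x + 3])
    return out


def brute_disk_area(radius):
    """Number of integer lattice points within Euclidean distance radius."""
    r = int(math.ceil(radius))
    return sum(
        1
        for y in range(-r, r + 1)
        for x in range(-r, r + 1)
        if math.hypot(y, x) <= radius
    )


def brute_bin(values, lo, hi, ng):
    """Clamp to [lo, hi] then linear binning into ng levels."""
    out = []
    for v in values:
        v = min(max(v, lo), hi)
        lv = int((v - lo) / (hi - lo) * ng)
        out.append(min(lv, ng - 1))
    return np.array(out)


def brute_nearest_rank(values, p):
    v = sorted(values)
    k = max(1, math.ceil(p * len(v)))
    return v[k - 1]


def brute_mw_enumeration(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    centre = n * m / 2
    count = total = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total
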