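"""Independent brute-force oracles used to validate the feature engine.

Everything here is written as direct, naive evaluation of the defining
formulas (explicit loops, dictionaries of voxels, manual interpolation),
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- first order

def percentile_linear(sorted_values, q):
    """q-th percentile with linear interpolation between order statistics."""
    n = len(sorted_values)
    h = (n - 1) * (q / 100.0)
    lo = int(math.floor(h))
    if lo >= n - 1:
        return float(sorted_values[-1])
    return float(sorted_values[lo] + (h - lo) * (sorted_values[lo + 1] - sorted_values[lo]))


def firstorder_oracle(values):
    """The 44 first-order statistics by direct formula evaluation."""
    v = [float(x) for x in values]
    n = len(v)
    s = sorted(v)
    mean = sum(v) / n
    median = percentile_linear(s, 50)

    counts = {}
    for x in v:
        counts[x] = counts.get(x, 0) + 1
    best = max(counts.values())
    mode = min(x for x, c in counts.items() if c == best)

    if n > 1 and s[0] != s[-1]:
        variance = sum((x - mean) ** 2 for x in v) / (n - 1)
        sd = math.sqrt(variance)
        m2 = sum((x - mean) ** 2 for x in v) / n
        m3 = sum((x - mean) ** 3 for x in v) / n
        m4 = sum((x - mean) ** 4 for x in v) / n
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0
        cv = sd / mean if mean != 0 else 0.0
        sem = sd / math.sqrt(n)
    else:
        variance = sd = skew = kurt = cv = sem = 0.0

    q1 = percentile_linear(s, 25)
    q3 = percentile_linear(s, 75)
    p10 = percentile_linear(s, 10)
    p90 = percentile_linear(s, 90)

    def trimmed(prop):
        k = int(math.floor(prop * n))
        sub = s[k:n - k]
        return sum(sub) / len(sub)

    def winsorized(prop):
        k = int(math.floor(prop * n))
        w = list(s)
        for idx in range(k):
            w[idx] = s[k]
            w[n - 1 - idx] = s[n - 1 - k]
        return sum(w) / n

    def entropy_uniformity(n_bins):
        vmin, vmax = s[0], s[-1]
        if vmax == vmin:
            return 0.0, 1.0
        width = (vmax - vmin) / n_bins
        occ = [0] * n_bins
        for x in v:
            b = min(n_bins - 1, int(math.floor((x - vmin) / width)))
            occ[b] += 1
        ps = [c / n for c in occ if c > 0]
        return -sum(p * math.log2(p) for p in ps), sum(p * p for p in ps)

    out = {
        "fo_mean": mean, "fo_median": median, "fo_mode": mode,
        "fo_sd": sd, "fo_variance": variance, "fo_skewness": skew,
        "fo_kurtosis": kurt, "fo_min": s[0], "fo_max": s[-1],
        "fo_range": s[-1] - s[0], "fo_iqr": q3 - q1,
        "fo_mad_mean": sum(abs(x - mean) for x in v) / n,
        "fo_mad_median": percentile_linear(sorted(abs(x - median) for x in v), 50),
        "fo_rms": math.sqrt(sum(x * x for x in v) / n),
        "fo_energy_density": sum(x * x for x in v) / n,
        "fo_cv": cv,
    }
    for p in (1, 5, 10, 20, 25, 30, 40, 60, 70, 75, 80, 90, 95, 99):
        out[f"fo_p{p}"] = percentile_linear(s, p)
    out["fo_trimmed_mean_5"] = trimmed(0.05)
    out["fo_trimmed_mean_10"] = trimmed(0.10)
    out["fo_winsorized_mean_5"] = winsorized(0.05)
    out["fo_midhinge"] = (q1 + q3) / 2.0
    for b in (16, 32, 64):
        ent, uni = entropy_uniformity(b)
        out[f"fo_entropy_b{b}"] = ent
        out[f"fo_uniformity_b{b}"] = uni
    out["fo_quartile_skewness"] = (q3 + q1 - 2 * median) / (q3 - q1) if q3 != q1 else 0.0
    out["fo_quartile_dispersion"] = (q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else 0.0
    out["fo_sem"] = sem
    out["fo_interdecile_range"] = p90 - p10
    return out


# -------------------------------------------------------------------- texture

def glcm_oracle(coords, bins, n_bins, offset, distance):
    """Symmetrized, normalized co-occurrence matrix by a double loop."""
    lookup = {tuple(c): b for c, b in zip(coords, bins)}
    mat = np.zeros((n_bins, n_bins))
    for c, b in lookup.items():
        nb = (c[0] + distance * offset[0], c[1] + distance * offset[1],
              c[2] + distance * offset[2])
        if nb in lookup:
            mat[b - 1, lookup[nb] - 1] += 1
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else mat


def glcm_stats_oracle(p):
    """The 19 co-occurrence statistics by naive looped formula evaluation."""
    B = p.shape[0]

    def log2(x):
        return math.log2(x) if x > 0 else 0.0

    px = [sum(p[i, j] for j in range(B)) for i in range(B)]
    mu = sum((i + 1) * px[i] for i in range(B))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(B))
    p_sum = {}
    p_diff = {}
    for i in range(B):
        for j in range(B):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i, j]
    sa = sum(k * v for k, v in p_sum.items())
    dm = sum(k * v for k, v in p_diff.items())
    hxy = -sum(p[i, j] * log2(p[i, j]) for i in range(B) for j in range(B))
    hx = -sum(q * log2(q) for q in px)
    hxy1 = -sum(p[i, j] * log2(px[i] * px[j]) for i in range(B) for j in range(B))
    hxy2 = -sum(px[i] * px[j] * log2(px[i] * px[j])
                for i in range(B) for j in range(B))
    autocorr = sum((i + 1) * (j + 1) * p[i, j] for i in range(B) for j in range(B))
    return {
        "asm": sum(p[i, j] ** 2 for i in range(B) for j in range(B)),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(B) for j in range(B)),
        "correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0,
        "variance": sigma2,
        "idm": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(B) for j in range(B)),
        "sum_average": sa,
        "sum_variance": sum((k - sa) ** 2 * v for k, v in p_sum.items()),
        "sum_entropy": -sum(v * log2(v) for v in p_sum.values()),
        "entropy": hxy,
        "difference_variance": sum((k - dm) ** 2 * v for k, v in p_diff.items()),
        "difference_entropy": -sum(v * log2(v) for v in p_diff.values()),
        "imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "max_probability": p.max(),
        "autocorrelation": autocorr,
        "cluster_shade": sum((i + j + 2 - 2 * mu) ** 3 * p[i, j]
                             for i in range(B) for j in range(B)),
        "cluster_prominence": sum((i + j + 2 - 2 * mu) ** 4 * p[i, j]
                                  for i in range(B) for j in range(B)),
        "dissimilarity": sum(abs(i - j) * p[i, j]
                             for i in range(B) for j in range(B)),
        "idn": sum(p[i, j] / (1 + abs(i - j) / B)
                   for i in range(B) for j in range(B)),
    }


def glrlm_oracle(coords, bins, n_bins, offset):
    """Run-length matrix by explicit run walking from every run start."""
    lookup = {tuple(c): b for c, b in zip(coords, bins)}
    runs = []
    for c, b in lookup.items():
        prev = (c[0] - offset[0], c[1] - offset[1], c[2] - offset[2])
        if prev in lookup and lookup[prev] == b:
            continue  # not a run start
        length = 1
        nxt = (c[0] + offset[0], c[1] + offset[1], c[2] + offset[2])
        while nxt in lookup and lookup[nxt] == b:
            length += 1
            nxt = (nxt[0] + offset[0], nxt[1] + offset[1], nxt[2] + offset[2])
        runs.append((b, length))
    lmax = max((l for _, l in runs), default=1)
    mat = np.zeros((n_bins, lmax), dtype=np.int64)
    for b, l in runs:
        mat[b - 1, l - 1] += 1
    return mat


def glrlm_stats_oracle(mat, n_voxels):
    """The 11 run statistics of one direction by looped formulas."""
    B, L = mat.shape
    nr = float(mat.sum())
    if nr == 0:
        return {k: 0.0 for k in ("sre", "lre", "gln", "rln", "rp", "lglre",
                                 "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle")}

    def total(f):
        return sum(f(i + 1, j + 1) * mat[i, j] for i in range(B) for j in range(L))

    return {
        "sre": total(lambda i, j: 1 / j ** 2) / nr,
        "lre": total(lambda i, j: j ** 2) / nr,
        "gln": sum(mat[i, :].sum() ** 2 for i in range(B)) / nr,
        "rln": sum(mat[:, j].sum() ** 2 for j in range(L)) / nr,
        "rp": nr / n_voxels,
        "lglre": total(lambda i, j: 1 / i ** 2) / nr,
        "hglre": total(lambda i, j: i ** 2) / nr,
        "srlgle": total(lambda i, j: 1 / (i ** 2 * j ** 2)) / nr,
        "srhgle": total(lambda i, j: i ** 2 / j ** 2) / nr,
        "lrlgle": total(lambda i, j: j ** 2 / i ** 2) / nr,
        "lrhgle": total(lambda i, j: i ** 2 * j ** 2) / nr,
    }


# ------------------------------------------------------------------- geometry

def surface_oracle(coords, spacing):
    """Exposed-face area by scanning each voxel's six neighbors."""
    sx, sy, sz = spacing
    areas = {(1, 0, 0): sy * sz, (-1, 0, 0): sy * sz,
             (0, 1, 0): sx * sz, (0, -1, 0): sx * sz,
             (0, 0, 1): sx * sy, (0, 0, -1): sx * sy}
    voxels = {tuple(c) for c in coords}
    total = 0.0
    for c in voxels:
        for (dx, dy, dz), a in areas.items():
            if (c[0] + dx, c[1] + dy, c[2] + dz) not in voxels:
                total += a
    return total


def box_count_oracle(coords, eps):
    """Number of occupied eps-boxes, grid anchored at the bounding-box origin."""
    coords = np.asarray(coords)
    origin = coords.min(axis=0)
    boxes = {tuple((c - origin) // eps) for c in coords}
    return len(boxes)


# ----------------------------------------------------------------- statistics

def auc_oracle(scores, labels):
    """AUC by counting positive-negative pairs (ties count 0.5)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def chi2_oracle(table):
    """Pearson chi-square statistic by the textbook formula."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i, :].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat


def robust_scale_oracle(column, x):
    """(x - median) / IQR with linear-interpolation quartiles."""
    s = sorted(column)
    med = percentile_linear(s, 50)
    iqr = percentile_linear(s, 75) - percentile_linear(s, 25)
    return (x - med) / iqr
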