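"""Independent brute-force oracles for the texture stage.

Deliberately naive (pure-Python double loops, no shared code with the
package) so they can serve as a second route for the GLCM builder and every
feature formula.
"""

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def naive_glcm(levels, mask, angle, distance, n_levels):
    """Bidirectional co-occurrence by explicit pair enumeration; returns the
    normalised symmetric matrix or None when no valid pair exists."""
    levels = np.asarray(levels)
    h, w = levels.shape
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[levels[r, c], levels[r2, c2]] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def _log2(x):
    return math.log2(x) if x > 0 else 0.0


def naive_features(P, sum_variance_about="sum_average"):
    """All 21 features evaluated directly from their definitions with
    1-based grey levels and base-2 logarithms."""
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    I = list(range(N))
    lev = lambda i: i + 1  # noqa: E731

    px = [sum(P[i][j] for j in I) for i in I]
    py = [sum(P[i][j] for i in I) for j in I]
    mu_x = sum(lev(i) * px[i] for i in I)
    mu_y = sum(lev(j) * py[j] for j in I)
    var_x = sum((lev(i) - mu_x) ** 2 * px[i] for i in I)
    var_y = sum((lev(j) - mu_y) ** 2 * py[j] for j in I)

    p_sum = {k: 0.0 for k in range(2, 2 * N + 1)}
    p_diff = {k: 0.0 for k in range(0, N)}
    for i in I:
        for j in I:
            p_sum[lev(i) + lev(j)] += P[i][j]
            p_diff[abs(lev(i) - lev(j))] += P[i][j]

    hxy = -sum(P[i][j] * _log2(P[i][j]) for i in I for j in I)
    hx = -sum(px[i] * _log2(px[i]) for i in I)
    hy = -sum(py[j] * _log2(py[j]) for j in I)
    hxy1 = -sum(P[i][j] * _log2(px[i] * py[j]) for i in I for j in I)
    hxy2 = -sum(px[i] * py[j] * _log2(px[i] * py[j]) for i in I for j in I)

    autocorr = sum(lev(i) * lev(j) * P[i][j] for i in I for j in I)
    sum_avg = sum(k * p for k, p in p_sum.items())
    sum_entropy = -sum(p * _log2(p) for p in p_sum.values())
    sv_centre = sum_avg if sum_variance_about == "sum_average" else sum_entropy
    mu_d = sum(k * p for k, p in p_diff.items())

    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "Autocorrelation": autocorr,
        "Cluster Prominence": sum((lev(i) + lev(j) - mu_x - mu_y) ** 4 * P[i][j]
                                  for i in I for j in I),
        "Cluster Shade": sum((lev(i) + lev(j) - mu_x - mu_y) ** 3 * P[i][j]
                             for i in I for j in I),
        "Contrast": sum((lev(i) - lev(j)) ** 2 * P[i][j] for i in I for j in I),
        "Correlation": correlation,
        "Difference Entropy": -sum(p * _log2(p) for p in p_diff.values()),
        "Difference Variance": sum((k - mu_d) ** 2 * p for k, p in p_diff.items()),
        "Dissimilarity": sum(abs(lev(i) - lev(j)) * P[i][j] for i in I for j in I),
        "Energy": sum(P[i][j] ** 2 for i in I for j in I),
        "Entropy": hxy,
        "Homogeneity": sum(P[i][j] / (1 + (lev(i) - lev(j)) ** 2)
                           for i in I for j in I),
        "IMC1": imc1,
        "IMC2": imc2,
        "Inverse Difference": sum(P[i][j] / (1 + abs(lev(i) - lev(j)))
                                  for i in I for j in I),
        "IDMN": sum(P[i][j] / (1 + (lev(i) - lev(j)) ** 2 / N ** 2)
                    for i in I for j in I),
        "IDN": sum(P[i][j] / (1 + abs(lev(i) - lev(j)) / N)
                   for i in I for j in I),
        "Maximum Probability": max(P[i][j] for i in I for j in I),
        "Sum Average": sum_avg,
        "Sum Entropy": sum_entropy,
        "SSV": sum((lev(i) - mu_x) ** 2 * P[i][j] for i in I for j in I),
        "Sum Variance": sum((k - sv_centre) ** 2 * p for k, p in p_sum.items()),
    }


def random_glcm(rng, n_levels, sparsity=0.0):
    """Random symmetric normalised co-occurrence matrix."""
    A = rng.random((n_levels, n_levels))
    if sparsity > 0:
        A *= rng.random((n_levels, n_levels)) > sparsity
    P = A + A.T
    if P.sum() == 0:
        P[0, 0] = 1.0
    return P / P.sum()
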