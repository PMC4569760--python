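"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — literal loops and
textbook formulas — and deliberately shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

# offsets matching distance-1 co-occurrence at 0/45/90/135 degrees
# (row, col), positive row = down; symmetric counting makes the sign moot
COOC_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def glcm_by_loops(q: np.ndarray, levels: int, angle_deg: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix by pair enumeration."""
    dr, dc = COOC_OFFSETS[angle_deg]
    h, w = q.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    return P / P.sum()


def glcm_stats_by_loops(P: np.ndarray) -> dict[str, float]:
    """Contrast/correlation/energy/homogeneity from the matrix definition."""
    levels = P.shape[0]
    i = np.arange(levels)
    pi = P.sum(axis=1)
    mu = (i * pi).sum()
    sigma = math.sqrt(((i - mu) ** 2 * pi).sum())
    contrast = energy = homogeneity = corr = 0.0
    for a in range(levels):
        for b in range(levels):
            p = P[a, b]
            contrast += p * (a - b) ** 2
            energy += p * p
            homogeneity += p / (1.0 + (a - b) ** 2)
            if sigma > 0:
                corr += p * (a - mu) * (b - mu) / sigma**2
    return {
        "contrast": contrast,
        "correlation": corr if sigma > 0 else 1.0,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def acf_by_loops(image: np.ndarray, axis: int, lag: int) -> float:
    """Normalized autocorrelation at one lag by explicit pair summation."""
    a = np.asarray(image, dtype=float)
    mu = a.mean()
    var = ((a - mu) ** 2).mean()
    h, w = a.shape
    total, count = 0.0, 0
    for r in range(h):
        for c in range(w):
            if axis == 0 and r + lag < h:
                total += (a[r, c] - mu) * (a[r + lag, c] - mu)
                count += 1
            elif axis == 1 and c + lag < w:
                total += (a[r, c] - mu) * (a[r, c + lag] - mu)
                count += 1
    return total / count / var


def moments_by_loops(coords: np.ndarray) -> tuple[float, float, float]:
    """Radial moments about the centroid by a literal per-pixel loop."""
    coords = np.asarray(coords, dtype=float)
    cy = sum(p[0] for p in coords) / len(coords)
    cx = sum(p[1] for p in coords) / len(coords)
    m1 = m2 = m3 = 0.0
    for r, c in coords:
        d = math.sqrt((r - cy) ** 2 + (c - cx) ** 2)
        m1 += d
        m2 += d * d
        m3 += d * d * d
    n = len(coords)
    return m1 / n, m2 / n, m3 / n


def auc_by_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the exhaustive pairwise concordance count."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def lasso_coordinate_descent(
    Z: np.ndarray, yc: np.ndarray, lam: float,
    tol: float = 1e-10, max_iter: int = 200_000,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2n)||yc - Zb||^2 + lam * ||b||_1."""
    n, p = Z.shape
    b = np.zeros(p)
    col_sq = (Z**2).sum(axis=0) / n
    r = yc.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = (Z[:, j] @ r) / n + col_sq[j] * old
            new = math.copysign(max(abs(rho) - lam, 0.0), rho) / col_sq[j]
            if new != old:
                r -= Z[:, j] * (new - old)
                b[j] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return b


def icc21_by_anova(scores: np.ndarray) -> float:
    """ICC(2,1) from hand-computed two-way ANOVA variance components."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    grand = scores.mean()
    ssr = sum(k * (scores[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (scores[:, j].mean() - grand) ** 2 for j in range(k))
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (scores[i, j] - scores[i].mean() - scores[:, j].mean() + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def histogram_stats_by_formula(v: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """The 14 histogram features computed from raw definitions."""
    v = np.sort(np.asarray(v, dtype=float).ravel())
    n = len(v)
    mean = v.sum() / n
    m2 = ((v - mean) ** 2).sum() / n
    sd = math.sqrt(m2)
    m3 = ((v - mean) ** 3).sum() / n
    m4 = ((v - mean) ** 4).sum() / n
    skew = m3 / sd**3
    kurt = m4 / sd**4 - 3.0
    median = float(np.percentile(v, 50))
    p10, p25, p75, p90 = (float(np.percentile(v, q)) for q in (10, 25, 75, 90))
    counts, edges = np.histogram(v, bins=n_bins)
    kmax = int(np.argmax(counts))
    mode = (edges[kmax] + edges[kmax + 1]) / 2
    p = counts / n
    entropy = -sum(pi * math.log(pi) for pi in p if pi > 0)
    energy = sum(pi * pi for pi in p)
    return {
        "mean": mean, "sd": sd, "skewness": skew, "kurtosis": kurt,
        "median": median, "mode": mode, "iqr": p75 - p25,
        "mode_over_iqr": mode / (p75 - p25),
        "entropy": entropy, "energy": energy,
        "p10": p10, "p90": p90, "p90_minus_p10": p90 - p10, "cv": sd / mean,
    }
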