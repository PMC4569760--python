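"""The 55-feature-per-image texture catalog (165 per transform stack).

Five feature classes are computed on each image of a
:class:`~fibrotex.standardize.TransformStack`:

==================  ==  =======================================================
class               n   summary
==================  ==  =======================================================
histogram           14  moments, quantiles and 64-bin histogram statistics of
                        the pixel-intensity distribution
gmm                  8  one- vs two-component Gaussian mixture fit to the
                        intensity sample (the two CCE pixel populations:
                        dark SPIO-loaded lobules, bright Gd-filled septa)
autocorrelation      8  axis-wise normalized autocorrelation at small lags,
                        correlation lengths and anisotropy
cooccurrence        16  gray-level co-occurrence contrast / correlation /
                        energy / homogeneity at distance 1, four directions
voronoi              9  inertial moments and areas of Voronoi polygons grown
                        from detected nodule centers (regional minima)
==================  ==  =======================================================

Feature names follow ``<source>.<class>.<feature>`` with source in
{original, gradient, laplacian}; a stack therefore yields exactly
3 x 55 = 165 named values.  Derivative images are min-max shift-normalized
internally before the histogram, gmm and cooccurrence classes (their
definitions assume a bounded intensity range); the autocorrelation class is
normalization-invariant and uses the raw field.

Degenerate inputs (constant images, too few Voronoi polygons) never produce
NaN: each class has fixed, documented imputation conventions, and
imputations are reported through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.feature import graycomatrix, graycoprops, peak_local_max

from .standardize import TransformStack, rescale_unit_interval

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCES",
    "CLASS_FEATURES",
    "FEATURE_NAMES",
    "VoronoiDecomposition",
    "histogram_features",
    "gmm_features",
    "autocorrelation_features",
    "normalized_acf",
    "cooccurrence_features",
    "voronoi_decompose",
    "voronoi_features",
    "polygon_moments",
    "extract_feature_vector",
    "average_subject_features",
    "feature_catalog",
]

SOURCES = ("original", "gradient", "laplacian")

_HIST_NAMES = (
    "mean", "sd", "skewness", "kurtosis", "median", "mode", "iqr",
    "mode_over_iqr", "entropy", "energy", "p10", "p90", "p90_minus_p10", "cv",
)
_GMM_NAMES = (
    "mean_low", "sd_low", "mean_high", "sd_high", "weight_low",
    "separation", "aic_ratio", "loglik_gain",
)
_ACF_NAMES = (
    "acf_lag1", "acf_lag2", "acf_lag4", "acf_lag8",
    "corr_length_row", "corr_length_col", "anisotropy", "acf_sum",
)
_COOC_ANGLES_DEG = (0, 45, 90, 135)
_COOC_STATS = ("contrast", "correlation", "energy", "homogeneity")
_COOC_NAMES = tuple(f"{s}_a{a}" for s in _COOC_STATS for a in _COOC_ANGLES_DEG)
_VORONOI_NAMES = (
    "mean_moment1", "sd_moment1", "mean_moment2", "sd_moment2",
    "mean_moment3", "sd_moment3", "mean_area", "sd_area", "density_per_cm2",
)

CLASS_FEATURES: dict[str, tuple[str, ...]] = {
    "histogram": _HIST_NAMES,
    "gmm": _GMM_NAMES,
    "autocorrelation": _ACF_NAMES,
    "cooccurrence": _COOC_NAMES,
    "voronoi": _VORONOI_NAMES,
}

#: canonical 165-name order: sources outer, classes inner, features innermost
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{src}.{cls}.{feat}"
    for src in SOURCES
    for cls, feats in CLASS_FEATURES.items()
    for feat in feats
)

_IQR_EPS = 1e-6
_N_HIST_BINS = 64


def histogram_features(image: np.ndarray, n_bins: int = _N_HIST_BINS) -> dict[str, float]:
    """Pixel-intensity histogram class (14 features).

    Mode, entropy (natural log) and energy use an ``n_bins`` equal-width
    histogram over [min, max].  A zero IQR imputes mode/IQR as mode/1e-6
    (logged); moments of a constant image are 0 by convention.
    """
    v = np.asarray(image, dtype=float).ravel()
    if v.size < 16:
        raise ValueError("histogram features need at least 16 pixels")
    mean = float(v.mean())
    sd = float(v.std())
    constant = sd == 0.0
    skew = 0.0 if constant else float(stats.skew(v))
    kurt = 0.0 if constant else float(stats.kurtosis(v))  # excess kurtosis
    median = float(np.median(v))
    p10, p25, p75, p90 = (float(q) for q in np.percentile(v, [10, 25, 75, 90]))
    iqr = p75 - p25

    if constant:
        mode = mean
        entropy = 0.0
        energy = 1.0
    else:
        counts, edges = np.histogram(v, bins=n_bins)
        k = int(np.argmax(counts))
        mode = float((edges[k] + edges[k + 1]) / 2.0)
        p = counts / counts.sum()
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        energy = float((p**2).sum())

    if iqr == 0.0:
        logger.info("histogram: zero IQR, imputing mode/IQR with eps=%g", _IQR_EPS)
        mode_over_iqr = mode / _IQR_EPS
    else:
        mode_over_iqr = mode / iqr
    cv = sd / mean if abs(mean) > 1e-12 else 0.0

    return dict(zip(_HIST_NAMES, (
        mean, sd, skew, kurt, median, mode, iqr, mode_over_iqr,
        entropy, energy, p10, p90, p90 - p10, cv,
    )))


def _gaussian_loglik(v: np.ndarray) -> float:
    var = max(v.var(), 1e-12)
    n = v.size
    return float(-0.5 * n * (np.log(2 * np.pi * var) + 1.0))


_EM_REG_VAR = 1e-9


def _em_two_component(
    v: np.ndarray,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Two-component 1-D Gaussian mixture by EM, restarts vectorized.

    Initialization is k-means++-style (first center a random data point,
    second drawn with probability proportional to squared distance);
    convergence when the mean log-likelihood changes by less than ``tol``.
    Returns (means, sds, weights, total log-likelihood, converged) of the
    best restart.
    """
    rng = np.random.default_rng(random_state)
    n = v.size
    mu = np.empty((n_init, 2))
    mu[:, 0] = v[rng.integers(0, n, n_init)]
    for r in range(n_init):
        d2 = (v - mu[r, 0]) ** 2
        tot = d2.sum()
        p = d2 / tot if tot > 0 else None
        mu[r, 1] = v[rng.choice(n, p=p)]
    var = np.full((n_init, 2), max(v.var(), _EM_REG_VAR))
    w = np.full((n_init, 2), 0.5)

    x = v[None, None, :]  # (1, 1, n)
    final_ll = np.full(n_init, -np.inf)
    converged = np.zeros(n_init, dtype=bool)
    active = np.arange(n_init)
    prev_ll = np.full(n_init, -np.inf)
    for _ in range(max_iter):
        if active.size == 0:
            break
        mu_a, var_a, w_a = mu[active], var[active], w[active]
        log_pdf = (
            -0.5 * (x - mu_a[:, :, None]) ** 2 / var_a[:, :, None]
            - 0.5 * np.log(2 * np.pi * var_a[:, :, None])
            + np.log(np.maximum(w_a[:, :, None], 1e-300))
        )
        m = log_pdf.max(axis=1, keepdims=True)
        log_norm = m[:, 0, :] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = log_norm.mean(axis=1)
        resp = np.exp(log_pdf - log_norm[:, None, :])
        nk = resp.sum(axis=2)  # (A, 2)
        w[active] = nk / n
        mu[active] = (resp * x).sum(axis=2) / np.maximum(nk, 1e-300)
        var_new = (resp * (x - mu[active][:, :, None]) ** 2).sum(axis=2) \
            / np.maximum(nk, 1e-300)
        var[active] = np.maximum(var_new, _EM_REG_VAR)
        final_ll[active] = ll
        done = np.abs(ll - prev_ll[active]) < tol
        prev_ll[active] = ll
        converged[active[done]] = True
        active = active[~done]
    best = int(np.argmax(final_ll))
    prev_ll = final_ll
    return (
        mu[best], np.sqrt(var[best]), w[best],
        float(prev_ll[best] * n), bool(converged[best]),
    )


def gmm_features(
    image: np.ndarray,
    max_pixels: int = 1024,
    n_init: int = 10,
    random_state: int = 0,
) -> dict[str, float]:
    """Gaussian-mixture class (8 features).

    Fits one- and two-component mixtures to the pixel-intensity sample by EM
    (k-means++ initialization, ``n_init`` restarts, tol 1e-6, <=500
    iterations).  The one-component fit has the closed-form Gaussian MLE.
    AIC = 2k - 2 lnL with k = 2 (single Gaussian) or 5 (mixture); components
    are ordered by mean, "low" = smaller mean.  Pixel samples larger than
    ``max_pixels`` are subsampled deterministically for the EM fit.
    """
    v = np.asarray(image, dtype=float).ravel()
    if v.size < 50:
        raise ValueError("gmm features need at least 50 pixels")
    if v.max() - v.min() < 1e-12:
        # texture-free image: one degenerate population by convention
        return dict(zip(_GMM_NAMES, (
            float(v[0]), 0.0, float(v[0]), 0.0, 1.0, 0.0, 1.0, 0.0,
        )))

    if v.size > max_pixels:
        sub = np.random.default_rng(random_state).choice(v.size, max_pixels, replace=False)
        v = v[sub]

    ll1 = _gaussian_loglik(v)
    aic1 = 2 * 2 - 2 * ll1

    means, sds, weights, ll2, converged = _em_two_component(
        v, n_init=n_init, random_state=random_state
    )
    if not converged:
        logger.warning("gmm: EM did not converge; using best attained fit")
    aic2 = 2 * 5 - 2 * ll2
    order = np.argsort(means)
    (mean_low, mean_high) = means[order]
    (sd_low, sd_high) = sds[order]
    (weight_low, _) = weights[order]
    pooled = float(np.sqrt(weights[order[0]] * sds[order[0]] ** 2
                           + weights[order[1]] * sds[order[1]] ** 2))
    separation = (mean_high - mean_low) / pooled if pooled > 0 else 0.0
    aic_ratio = aic2 / aic1 if abs(aic1) > 1e-12 else 1.0

    return dict(zip(_GMM_NAMES, (
        float(mean_low), float(sd_low), float(mean_high), float(sd_high),
        float(weight_low), float(separation), float(aic_ratio), float(ll2 - ll1),
    )))


def normalized_acf(image: np.ndarray, axis: int, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation along one axis for lags 1..max_lag.

    Mean-removed, variance-normalized; products averaged over all valid
    (non-circular) pixel pairs.  Returns zeros for a constant image.
    """
    a = np.asarray(image, dtype=float)
    a = a - a.mean()
    var = float((a * a).mean())
    out = np.zeros(max_lag)
    if var <= 1e-18:
        return out
    for k in range(1, max_lag + 1):
        if axis == 0:
            prod = a[:-k, :] * a[k:, :]
        else:
            prod = a[:, :-k] * a[:, k:]
        out[k - 1] = float(prod.mean()) / var
    return out


def _correlation_length(acf: np.ndarray) -> float:
    """First lag (linearly interpolated) at which the ACF drops below 1/e."""
    target = 1.0 / np.e
    prev_lag, prev_val = 0.0, 1.0
    for k, val in enumerate(acf, start=1):
        if val < target:
            return prev_lag + (prev_val - target) / (prev_val - val)
        prev_lag, prev_val = float(k), float(val)
    return float(len(acf))


def autocorrelation_features(image: np.ndarray, max_lag: int = 8) -> dict[str, float]:
    """Autocorrelation class (8 features).

    ACF at lags 1, 2, 4, 8 averaged over the two axes; per-axis correlation
    lengths (1/e crossing); anisotropy = column length / row length; and the
    sum of the axis-averaged ACF over lags 1..8.  A zero-variance image
    yields all-zero ACF values, zero lengths and unit anisotropy.
    """
    a = np.asarray(image, dtype=float)
    if min(a.shape) < 2 * max_lag:
        raise ValueError(f"autocorrelation features need both dimensions >= {2 * max_lag}")
    if a.max() - a.min() < 1e-15:
        return dict(zip(_ACF_NAMES, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0)))
    acf_row = normalized_acf(a, axis=0, max_lag=max_lag)
    acf_col = normalized_acf(a, axis=1, max_lag=max_lag)
    acf_avg = (acf_row + acf_col) / 2.0
    len_row = _correlation_length(acf_row)
    len_col = _correlation_length(acf_col)
    anisotropy = len_col / len_row if len_row > 0 else 1.0
    return dict(zip(_ACF_NAMES, (
        float(acf_avg[0]), float(acf_avg[1]), float(acf_avg[3]), float(acf_avg[7]),
        len_row, len_col, float(anisotropy), float(acf_avg.sum()),
    )))


_N_GRAY_LEVELS = 16


def quantize_gray_levels(image: np.ndarray, levels: int = _N_GRAY_LEVELS) -> np.ndarray:
    """Equal-width quantization of [min, max] into ``levels`` integer levels."""
    a = np.asarray(image, dtype=float)
    span = a.max() - a.min()
    if span <= 0:
        return np.zeros(a.shape, dtype=np.uint8)
    q = np.floor((a - a.min()) / span * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def cooccurrence_features(image: np.ndarray, levels: int = _N_GRAY_LEVELS) -> dict[str, float]:
    """Gray-level co-occurrence class (16 features).

    Symmetric, normalized co-occurrence matrices at distance 1 and angles
    0/45/90/135 degrees on the ``levels``-level equal-width quantization;
    contrast, correlation, energy and homogeneity per angle.  A constant
    image returns contrast 0, energy 1, homogeneity 1, and correlation 0 by
    convention.
    """
    a = np.asarray(image, dtype=float)
    if a.max() - a.min() <= 0:
        out: dict[str, float] = {}
        for s in _COOC_STATS:
            for ang in _COOC_ANGLES_DEG:
                out[f"{s}_a{ang}"] = {"contrast": 0.0, "correlation": 0.0,
                                      "energy": 1.0, "homogeneity": 1.0}[s]
        return out
    q = quantize_gray_levels(a, levels)
    angles = [np.deg2rad(d) for d in _COOC_ANGLES_DEG]
    glcm = graycomatrix(q, distances=[1], angles=angles, levels=levels,
                        symmetric=True, normed=True)
    out = {}
    for s in _COOC_STATS:
        # "energy" here is the angular second moment (sum of squared joint
        # probabilities); skimage's 'energy' is its square root
        vals = graycoprops(glcm, "ASM" if s == "energy" else s)[0]
        for ang, val in zip(_COOC_ANGLES_DEG, vals):
            out[f"{s}_a{ang}"] = float(val)
    return out


@dataclass
class VoronoiDecomposition:
    """Voronoi tessellation of detected nodule centers, clipped to the image.

    ``polygons`` are interior (non-border-touching) cells as (n, 2) integer
    pixel-coordinate arrays; they are disjoint by construction.
    """

    seed_points: np.ndarray  # (k, 2) row/col, all detected minima
    polygons: list[np.ndarray]
    image_shape: tuple[int, int]
    pixel_spacing_mm: float = 0.5

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)


def voronoi_decompose(
    image: np.ndarray,
    smoothing_sigma_px: float = 1.0,
    min_seed_separation_px: int = 3,
    pixel_spacing_mm: float = 0.5,
) -> VoronoiDecomposition:
    """Tessellate an image into nodule-centered Voronoi polygons.

    Seeds are regional minima of the Gaussian-smoothed image (minima closer
    than ``min_seed_separation_px`` are suppressed, keeping the deeper one).
    Each pixel is assigned to its nearest seed; cells touching the image
    border are discarded as clipping artifacts, as are cells of fewer than
    3 pixels.

    Raises
    ------
    ValueError
        "insufficient nodule structure" when fewer than 4 seeds are found
        (including any constant image).
    """
    a = np.asarray(image, dtype=float)
    sm = ndimage.gaussian_filter(a, smoothing_sigma_px)
    if sm.max() - sm.min() < 1e-12:
        raise ValueError("insufficient nodule structure: image has no regional minima")
    seeds = peak_local_max(
        sm.max() - sm, min_distance=min_seed_separation_px, exclude_border=False
    )
    if len(seeds) < 4:
        raise ValueError(
            f"insufficient nodule structure: {len(seeds)} seeds detected (need >= 4)"
        )

    h, w = a.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    owner = cKDTree(seeds.astype(float)).query(pts, k=1)[1].reshape(h, w)

    border_owners = set(np.unique(owner[0, :])) | set(np.unique(owner[-1, :])) \
        | set(np.unique(owner[:, 0])) | set(np.unique(owner[:, -1]))
    polygons = []
    for i in range(len(seeds)):
        if i in border_owners:
            continue
        coords = np.column_stack(np.nonzero(owner == i))
        if len(coords) >= 3:
            polygons.append(coords)
    return VoronoiDecomposition(
        seed_points=seeds, polygons=polygons,
        image_shape=(h, w), pixel_spacing_mm=pixel_spacing_mm,
    )


def polygon_moments(coords: np.ndarray) -> tuple[float, float, float]:
    """Radial inertial moments of a pixel set about its centroid.

    moment_n = mean over pixels of |r - centroid|^n, in pixel units.
    """
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0)
    r = np.linalg.norm(coords - c, axis=1)
    return float(r.mean()), float((r**2).mean()), float((r**3).mean())


def voronoi_features(decomp: VoronoiDecomposition) -> dict[str, float]:
    """Voronoi polygon class (9 features).

    Mean and SD over retained polygons of the 1st/2nd/3rd radial inertial
    moments and of polygon area (pixels), plus polygon count density per
    cm² of image area.
    """
    if decomp.n_polygons < 4:
        raise ValueError(
            f"voronoi features need >= 4 interior polygons, got {decomp.n_polygons}"
        )
    m = np.array([polygon_moments(p) for p in decomp.polygons])
    areas = np.array([len(p) for p in decomp.polygons], dtype=float)
    h, w = decomp.image_shape
    area_cm2 = h * w * decomp.pixel_spacing_mm**2 / 100.0
    return dict(zip(_VORONOI_NAMES, (
        float(m[:, 0].mean()), float(m[:, 0].std()),
        float(m[:, 1].mean()), float(m[:, 1].std()),
        float(m[:, 2].mean()), float(m[:, 2].std()),
        float(areas.mean()), float(areas.std()),
        float(decomp.n_polygons / area_cm2),
    )))


def extract_feature_vector(
    stack: TransformStack,
    voronoi_sigma_px: float = 1.0,
    voronoi_min_separation_px: int = 3,
) -> dict[str, float]:
    """All 165 features of a transform stack, in the canonical name order.

    Derivative (gradient/Laplacian) images are min-max shift-normalized
    before the histogram, gmm and cooccurrence classes.  A Voronoi failure
    on any image imputes that class's 9 entries as 0 (logged), so the
    165-entry contract always holds.
    """
    out: dict[str, float] = {}
    for src in SOURCES:
        img = getattr(stack, src)
        bounded = img if src == "original" else rescale_unit_interval(img)
        for cls in CLASS_FEATURES:
            if cls == "histogram":
                vals = histogram_features(bounded)
            elif cls == "gmm":
                vals = gmm_features(bounded)
            elif cls == "autocorrelation":
                vals = autocorrelation_features(img)
            elif cls == "cooccurrence":
                vals = cooccurrence_features(bounded)
            else:
                try:
                    decomp = voronoi_decompose(
                        bounded, voronoi_sigma_px, voronoi_min_separation_px,
                        stack.pixel_spacing_mm,
                    )
                    vals = voronoi_features(decomp)
                except ValueError as exc:
                    logger.warning("voronoi class imputed as 0 on %s image: %s", src, exc)
                    vals = {name: 0.0 for name in _VORONOI_NAMES}
            for feat, val in vals.items():
                out[f"{src}.{cls}.{feat}"] = float(val)
    assert tuple(out) == FEATURE_NAMES
    return out


def average_subject_features(vectors: list[dict[str, float]]) -> dict[str, float]:
    """Element-wise mean of per-ROI feature vectors (the per-subject vector)."""
    if not vectors:
        raise ValueError("need at least one feature vector")
    names = tuple(vectors[0])
    for v in vectors[1:]:
        if tuple(v) != names:
            raise ValueError("feature vectors have mismatched name sets")
    arr = np.array([[v[n] for n in names] for v in vectors])
    return dict(zip(names, arr.mean(axis=0)))


def feature_catalog() -> list[dict[str, str]]:
    """Machine-readable catalog of the 165 features (name, source, class)."""
    catalog = []
    for name in FEATURE_NAMES:
        src, cls, feat = name.split(".", 2)
        catalog.append({"name": name, "source": src, "class": cls, "feature": feat})
    return catalog
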