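"""Histology comparison statistics, ROC analysis, and stain segmentation.

* Pearson/Spearman correlations between predicted and histologic scores.
* Two-way random-effects, absolute-agreement, single-rater ICC — ICC(2,1),
  the standard reading of "two-way analysis for precise agreement" — with
  F-distribution confidence intervals, plus pairwise reader ICCs.
* ROC analysis of the continuous texture score against a dichotomized
  reference (Metavir F-thresholds or %-collagen thresholds).  The primary
  operating cutoff maximizes sensitivity + specificity (the Youden point;
  ties resolve to the lower cutoff); the point closest to (0, 1) is also
  reported.  Confidence intervals are stratified percentile bootstrap.
* %-collagen measurement from a trichrome-stained RGB image: saturation
  adjustment, blue-dominance score B - max(R, G), manual intensity
  threshold, collagen fraction = blue pixels / tissue pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "ROCResult",
    "ICCResult",
    "correlation",
    "icc_two_way",
    "pairwise_iccs",
    "roc_analysis",
    "evaluate_all_thresholds",
    "roc_table",
    "collagen_fraction_from_stain",
    "METAVIR_THRESHOLDS",
    "COLLAGEN_THRESHOLDS",
]

METAVIR_THRESHOLDS = (1.0, 2.0, 3.0, 4.0)
COLLAGEN_THRESHOLDS = (5.0, 10.0, 15.0, 20.0)


def correlation(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlation needs two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method: {method}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ICCResult:
    """Two-way absolute-agreement single-rater ICC with its 95% CI."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int


def icc_two_way(scores: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) on an (n_subjects x n_raters) complete score matrix.

    Two-way random-effects ANOVA mean squares give the point estimate

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    and the confidence interval uses the F-distribution method with a
    Satterthwaite-approximated denominator degrees of freedom.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D subjects-by-raters matrix")
    n, k = scores.shape
    if n < 5 or k < 2:
        raise ValueError("ICC needs >= 5 subjects and >= 2 raters")
    if np.isnan(scores).any():
        raise ValueError("ICC needs a complete matrix")
    if scores.max() - scores.min() == 0:
        raise ValueError("ICC undefined for a constant score matrix")

    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = scores - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # F-based CI (two-way random, absolute agreement, single rater)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:  # perfect agreement
        ci_low = ci_high = icc
    return ICCResult(icc=float(icc), ci_low=float(min(ci_low, icc)),
                     ci_high=float(max(ci_high, icc)),
                     n_subjects=n, n_raters=k)


def pairwise_iccs(scores: np.ndarray) -> dict[tuple[int, int], float]:
    """ICC(2,1) for every rater pair of the score matrix."""
    scores = np.asarray(scores, dtype=float)
    _, k = scores.shape
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            out[(i, j)] = icc_two_way(scores[:, [i, j]]).icc
    return out


def _auc_rank(predicted: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (tie-aware; equals the
    trapezoidal area over all distinct cutoffs)."""
    ranks = stats.rankdata(predicted)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _operating_points(predicted: np.ndarray, labels: np.ndarray):
    """Sensitivity/specificity at every distinct cutoff (positive iff score >= c)."""
    cutoffs = np.unique(predicted)
    pos = predicted[labels]
    neg = predicted[~labels]
    sens = (pos[:, None] >= cutoffs[None, :]).mean(axis=0)
    spec = (neg[:, None] < cutoffs[None, :]).mean(axis=0)
    return cutoffs, sens, spec


def _metrics_at_cutoff(predicted, labels, cutoff):
    pred_pos = predicted >= cutoff
    n1 = labels.sum()
    n0 = len(labels) - n1
    sens = float((pred_pos & labels).sum() / n1) if n1 else np.nan
    spec = float((~pred_pos & ~labels).sum() / n0) if n0 else np.nan
    acc = float((pred_pos == labels).mean())
    return sens, spec, acc


@dataclass
class ROCResult:
    """One dichotomized classification analysis of the texture score."""

    threshold_definition: str
    dichotomize_at: float
    cutoff: float
    cutoff_closest01: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_positive: int = 0
    n_negative: int = 0


def roc_analysis(
    predicted: np.ndarray,
    reference: np.ndarray,
    dichotomize_at: float,
    reference_kind: str = "metavir",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC analysis of a continuous score against ``reference >= dichotomize_at``.

    AUC is the Mann-Whitney concordance (trapezoidal area); the operating
    cutoff maximizes sensitivity + specificity with ties resolved to the
    lower cutoff.  ``n_boot`` stratified percentile-bootstrap resamples give
    95% CIs for AUC, sensitivity, specificity and accuracy (sens/spec/acc
    held at the full-sample cutoff); ``n_boot=0`` skips the bootstrap.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    labels = reference >= dichotomize_at
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if reference_kind == "metavir":
        tdef = f"F <{dichotomize_at:g} versus F >={dichotomize_at:g}"
    else:
        tdef = f"<{dichotomize_at:g}% versus >={dichotomize_at:g}%"
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"threshold {tdef!r} leaves a single class "
            f"({n1} positive, {n0} negative)"
        )

    auc = _auc_rank(predicted, labels)
    cutoffs, sens_all, spec_all = _operating_points(predicted, labels)
    youden = sens_all + spec_all
    best = np.nonzero(youden == youden.max())[0]
    cutoff = float(cutoffs[best[0]])  # ties -> lower cutoff
    d01 = (1 - sens_all) ** 2 + (1 - spec_all) ** 2
    cutoff_closest01 = float(cutoffs[int(np.argmin(d01))])
    sens, spec, acc = _metrics_at_cutoff(predicted, labels, cutoff)

    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos_idx = np.nonzero(labels)[0]
        neg_idx = np.nonzero(~labels)[0]
        boot = np.empty((n_boot, 4))
        for b in range(n_boot):
            idx = np.concatenate([
                rng.choice(pos_idx, size=n1, replace=True),
                rng.choice(neg_idx, size=n0, replace=True),
            ])
            p_b, l_b = predicted[idx], labels[idx]
            boot[b, 0] = _auc_rank(p_b, l_b)
            boot[b, 1:] = _metrics_at_cutoff(p_b, l_b, cutoff)
        for j, name in enumerate(("auc", "sensitivity", "specificity", "accuracy")):
            lo, hi = np.percentile(boot[:, j], [2.5, 97.5])
            ci[name] = (float(lo), float(hi))

    return ROCResult(
        threshold_definition=tdef,
        dichotomize_at=float(dichotomize_at),
        cutoff=cutoff,
        cutoff_closest01=cutoff_closest01,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ci=ci,
        n_positive=n1,
        n_negative=n0,
    )


def evaluate_all_thresholds(
    predicted: np.ndarray,
    reference: np.ndarray,
    kind: str = "metavir",
    thresholds: tuple[float, ...] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[ROCResult | None]:
    """One ROC analysis per classification threshold.

    Metavir thresholds F1–F4 (classification F < t versus F >= t) or
    collagen thresholds 5/10/15/20%.  A threshold that leaves one class
    empty yields ``None`` in its slot; the others are still computed.
    """
    if thresholds is None:
        thresholds = METAVIR_THRESHOLDS if kind == "metavir" else COLLAGEN_THRESHOLDS
    results: list[ROCResult | None] = []
    for i, t in enumerate(thresholds):
        try:
            results.append(
                roc_analysis(predicted, reference, t, kind, n_boot=n_boot, seed=seed + i)
            )
        except ValueError:
            results.append(None)
    return results


def roc_table(results: list[ROCResult | None]) -> pd.DataFrame:
    """Render ROC results as a classification-performance table."""

    def fmt(value, ci):
        if ci is None:
            return f"{value:.3f}"
        return f"{value:.3f} [{ci[0]:.3f} {ci[1]:.3f}]"

    rows = []
    for r in results:
        if r is None:
            rows.append({"Classification": "(single class — not evaluable)"})
            continue
        rows.append({
            "Classification": r.threshold_definition,
            "Cutoff": round(r.cutoff, 3),
            "Area under curve": fmt(r.auc, r.ci.get("auc")),
            "Sensitivity": fmt(r.sensitivity, r.ci.get("sensitivity")),
            "Specificity": fmt(r.specificity, r.ci.get("specificity")),
            "Accuracy": fmt(r.accuracy, r.ci.get("accuracy")),
        })
    return pd.DataFrame(rows)


def collagen_fraction_from_stain(
    rgb_image: np.ndarray,
    saturation_adjust: float = 1.0,
    intensity_threshold: float = 0.2,
    tissue_mask: np.ndarray | None = None,
) -> float:
    """%-collagen from a trichrome-stained RGB image.

    Color saturation is scaled by ``saturation_adjust`` (stain-variability
    correction); a pixel counts as collagen when its blue-dominance score
    ``B - max(R, G)`` exceeds ``intensity_threshold`` (unit intensity
    scale).  Returns 100 * collagen pixels / tissue pixels.
    """
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    if img.max() > 1.0:
        img = img / 255.0
    if tissue_mask is None:
        tissue_mask = np.ones(img.shape[:2], dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")

    if saturation_adjust != 1.0:
        hsv = rgb2hsv(img)
        hsv[..., 1] = np.clip(hsv[..., 1] * saturation_adjust, 0.0, 1.0)
        img = hsv2rgb(hsv)

    blue_dominance = img[..., 2] - np.maximum(img[..., 0], img[..., 1])
    n_collagen = int((blue_dominance[tissue_mask] > intensity_threshold).sum())
    return 100.0 * n_collagen / n_tissue
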