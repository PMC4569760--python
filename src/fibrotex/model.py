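"""L1 regularization-path linear models with AIC selection.

The fibrosis predictors are sparse linear models of the 165 texture
features, obtained by following the lasso path (squared-error loss, L1
penalty) from the all-zero solution at ``lambda_max`` down a log-spaced
grid, and picking the path point that minimizes a Gaussian AIC

    AIC(lambda) = RSS(lambda) / sigma0^2 + 2 * (df + 1),

where df is the active-set size (the standard lasso degrees-of-freedom
estimate), the +1 accounts for the variance parameter, and the dispersion
sigma0^2 is the null-model variance of the response — the only variance
estimate available without selection bias when the feature count exceeds
the sample size.  This is the deviance + 2*df*dispersion form used by
path-following GLM software.  The profile form n*ln(RSS/n) + 2(df+1),
which treats the variance as jointly estimated, is also available
(``dispersion="profile"``) but degenerates whenever the path can
interpolate (p >= n drives RSS to ~0 and the criterion to -inf, selecting
saturated models); the fixed-dispersion form stays sparse in exactly the
p >> n regime these models are fit in.  Features are
z-scored internally; reported coefficients are back-transformed to the
original feature scale, and the intercept is never penalized.  Ties in AIC
resolve to the larger lambda (the sparser model).

Two reference standards give two models: mean Metavir reader score
(qualitative histology) and %-collagen (quantitative histology).  No
held-out validation is performed; the regularization itself is the guard
against overfitting, and in-sample optimism is expected and documented.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

__all__ = [
    "RegularizationPath",
    "PredictionModel",
    "fit_lasso_path",
    "select_by_aic",
    "predict_score",
    "fit_fibrosis_models",
]


@dataclass
class RegularizationPath:
    """Lasso solutions along a decreasing lambda grid.

    ``coefs_std`` holds standardized-scale coefficients (p x L);
    ``coefs_orig`` and ``intercepts`` are on the original feature scale.
    """

    lambda_grid: np.ndarray
    coefs_std: np.ndarray
    coefs_orig: np.ndarray
    intercepts: np.ndarray
    active_set_sizes: np.ndarray
    aic_trace: np.ndarray
    rss: np.ndarray
    feature_names: list[str]
    n: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float


@dataclass
class PredictionModel:
    """A selected sparse linear predictor of a fibrosis reference score.

    ``selected_features`` are ordered strongest to weakest by absolute
    standardized coefficient; ``coefficients`` (same order) are on the
    original feature scale, so prediction is
    ``intercept + sum(coef * feature)``.
    """

    selected_features: list[str]
    coefficients: list[float]
    intercept: float
    reference_type: str
    standardization_stats: dict[str, tuple[float, float]]
    lambda_: float
    aic: float
    aic_trace: list[float] = field(default_factory=list)
    lambda_grid: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "reference_type": self.reference_type,
            "standardization_stats": {
                k: list(v) for k, v in self.standardization_stats.items()
            },
            "lambda": self.lambda_,
            "aic": self.aic,
            "aic_trace": self.aic_trace,
            "lambda_grid": self.lambda_grid,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            selected_features=d["selected_features"],
            coefficients=d["coefficients"],
            intercept=d["intercept"],
            reference_type=d["reference_type"],
            standardization_stats={
                k: tuple(v) for k, v in d["standardization_stats"].items()
            },
            lambda_=d["lambda"],
            aic=d["aic"],
            aic_trace=d.get("aic_trace", []),
            lambda_grid=d.get("lambda_grid", []),
        )


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    dispersion: str = "null",
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> RegularizationPath:
    """Compute the lasso path on z-scored features.

    The grid is log-spaced from ``lambda_max`` (smallest penalty giving the
    all-zero solution, ``max |Z'y_c| / n``) down to
    ``lambda_min_ratio * lambda_max``.  Zero-variance columns are dropped
    with a warning.  The penalty convention is
    ``(1/2n) ||y - Zb||^2 + lambda ||b||_1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 8:
        raise ValueError("need at least 8 samples to fit a path")
    if len(y) != n:
        raise ValueError("X and y have mismatched lengths")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("feature matrix and response must be complete (no NaN)")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    keep = x_sd > 0
    if not keep.all():
        dropped = [feature_names[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}")
    Z = (X[:, keep] - x_mean[keep]) / x_sd[keep]
    y_mean = float(y.mean())
    yc = y - y_mean

    lambda_max = float(np.abs(Z.T @ yc).max() / n)
    if lambda_max <= 0:
        lambda_max = 1e-12
    lambdas = np.logspace(
        np.log10(lambda_max), np.log10(lambda_max * lambda_min_ratio), n_lambdas
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        _, coefs_kept, _ = lasso_path(
            Z, yc, alphas=lambdas, tol=tol, max_iter=max_iter
        )

    coefs_std = np.zeros((p, n_lambdas))
    coefs_std[keep, :] = coefs_kept
    preds = Z @ coefs_kept + y_mean
    rss = ((y[:, None] - preds) ** 2).sum(axis=0)
    df = (np.abs(coefs_kept) > 0).sum(axis=0)
    if dispersion == "null":
        sigma0_sq = max(float(yc.var()), 1e-300)
        aic = rss / sigma0_sq + 2 * (df + 1)
    elif dispersion == "profile":
        aic = n * np.log(np.maximum(rss, 1e-300) / n) + 2 * (df + 1)
    else:
        raise ValueError(f"unknown dispersion rule: {dispersion}")

    coefs_orig = np.zeros((p, n_lambdas))
    coefs_orig[keep, :] = coefs_kept / x_sd[keep][:, None]
    intercepts = y_mean - x_mean @ coefs_orig

    return RegularizationPath(
        lambda_grid=lambdas,
        coefs_std=coefs_std,
        coefs_orig=coefs_orig,
        intercepts=intercepts,
        active_set_sizes=df.astype(int),
        aic_trace=aic,
        rss=rss,
        feature_names=list(feature_names),
        n=n,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
    )


def select_by_aic(
    path: RegularizationPath,
    reference_type: str = "metavir",
    max_predictors: int | None = None,
) -> PredictionModel:
    """Pick the path point minimizing AIC (ties resolve to larger lambda).

    ``max_predictors`` optionally restricts the search to path points with
    at most that many active features, for fixed-size comparison tables.
    """
    aic = path.aic_trace.copy()
    if max_predictors is not None:
        aic = np.where(path.active_set_sizes <= max_predictors, aic, np.inf)
        if not np.isfinite(aic).any():
            raise ValueError("no path point satisfies the max_predictors constraint")
    # grid is in decreasing lambda order, so the first argmin is the sparsest
    idx = int(np.argmin(aic))

    beta_std = path.coefs_std[:, idx]
    active = np.nonzero(np.abs(beta_std) > 0)[0]
    order = active[np.argsort(-np.abs(beta_std[active]))]
    selected = [path.feature_names[i] for i in order]
    coefs = [float(path.coefs_orig[i, idx]) for i in order]
    stats = {
        path.feature_names[i]: (float(path.x_mean[i]), float(path.x_sd[i]))
        for i in order
    }
    return PredictionModel(
        selected_features=selected,
        coefficients=coefs,
        intercept=float(path.intercepts[idx]),
        reference_type=reference_type,
        standardization_stats=stats,
        lambda_=float(path.lambda_grid[idx]),
        aic=float(path.aic_trace[idx]),
        aic_trace=[float(a) for a in path.aic_trace],
        lambda_grid=[float(l) for l in path.lambda_grid],
    )


def predict_score(model: PredictionModel, features: dict[str, float]) -> float:
    """Affine prediction ``intercept + sum(coef * feature)``; no clipping.

    Predicted Metavir may fall outside [0, 4]: the model output is a
    continuous texture score, and classification cutoffs live on that scale.
    """
    total = model.intercept
    for name, coef in zip(model.selected_features, model.coefficients):
        if name not in features:
            raise KeyError(f"missing feature required by the model: {name}")
        total += coef * features[name]
    return float(total)


def predict_table(model: PredictionModel, table: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`predict_score` over a subjects-by-features table."""
    missing = [f for f in model.selected_features if f not in table.columns]
    if missing:
        raise KeyError(f"missing features required by the model: {missing}")
    if not model.selected_features:
        return np.full(len(table), model.intercept)
    sub = table[model.selected_features].to_numpy(dtype=float)
    return sub @ np.asarray(model.coefficients) + model.intercept


def fit_fibrosis_models(
    feature_table: pd.DataFrame,
    metavir_mean: np.ndarray,
    collagen_pct: np.ndarray,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    max_predictors: int | None = None,
) -> tuple[PredictionModel, PredictionModel]:
    """Fit the qualitative (Metavir) and quantitative (%-collagen) models.

    Both models are fit on the same per-subject feature matrix (rows =
    subjects, columns = the 165 features), each selected by AIC along its
    own lasso path.
    """
    X = feature_table.to_numpy(dtype=float)
    names = list(feature_table.columns)
    models = []
    for y, kind in ((metavir_mean, "metavir"), (collagen_pct, "collagen")):
        path = fit_lasso_path(X, np.asarray(y, dtype=float), names,
                              n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio)
        models.append(select_by_aic(path, reference_type=kind,
                                    max_predictors=max_predictors))
    return models[0], models[1]
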