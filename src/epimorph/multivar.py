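"""Multivariable prediction of histone-mark levels from morphology.

Cross-validated single- and multi-feature prediction with ordinary least
squares or a squared-exponential (RBF) kernel regressor, accuracy scored as
the Pearson r between out-of-fold predictions and measured values;
single-feature dropout importance; canonical correlation analysis between
the cellular and nuclear feature blocks; and PCA biplot data.

For DAPI-normalised histone targets, the DAPI mean/sd/CV predictors are
excluded automatically — their direct arithmetic relationship to a
mark/DAPI target carries no biological signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "PredictionResult",
    "ImportanceRanking",
    "CCAResult",
    "PCAResult",
    "SquaredExponentialRegressor",
    "predict",
    "dropout_importance",
    "cca_predict",
    "pca_biplot_data",
    "DAPI_EXCLUDED_PREDICTORS",
]

DAPI_EXCLUDED_PREDICTORS = ("DAPI_mean", "DAPI_sd", "DAPI_cv")


class SquaredExponentialRegressor(BaseEstimator, RegressorMixin):
    """Kernel-ridge regressor with a squared-exponential (RBF) kernel.

    The length-scale grid is the median pairwise-distance heuristic scaled
    by ``length_scale_factors``, and the noise/ridge level ranges over
    ``alphas``; both are selected by inner cross-validated MSE. Inputs and
    the target are standardised internally, so the estimator can be dropped
    into sklearn model selection directly.
    """

    def __init__(self, length_scale_factors=(0.25, 1.0, 4.0),
                 alphas=(1e-3, 1e-2, 1e-1), inner_folds: int = 3,
                 random_state: int = 0):
        self.length_scale_factors = length_scale_factors
        self.alphas = alphas
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _median_heuristic(self, X: np.ndarray) -> float:
        rng = np.random.default_rng(self.random_state)
        m = min(400, X.shape[0])
        idx = rng.choice(X.shape[0], size=m, replace=False)
        S = X[idx]
        d2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=-1)
        med = np.median(np.sqrt(d2[np.triu_indices(m, k=1)]))
        return float(med) if med > 0 else 1.0

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        self._x_scaler = StandardScaler().fit(X)
        Xs = self._x_scaler.transform(X)
        self._y_mean = float(np.mean(y))
        self._y_std = float(np.std(y)) or 1.0
        ys = (y - self._y_mean) / self._y_std

        ell0 = self._median_heuristic(Xs)
        best = (np.inf, None, None)
        kf = KFold(n_splits=min(self.inner_folds, len(ys)),
                   shuffle=True, random_state=self.random_state)
        for fac in self.length_scale_factors:
            gamma = 1.0 / (2.0 * (fac * ell0) ** 2)
            for alpha in self.alphas:
                mse = 0.0
                for tr, te in kf.split(Xs):
                    m = KernelRidge(kernel="rbf", gamma=gamma, alpha=alpha)
                    m.fit(Xs[tr], ys[tr])
                    mse += float(np.mean((m.predict(Xs[te]) - ys[te]) ** 2))
                if mse < best[0]:
                    best = (mse, gamma, alpha)
        _, self.gamma_, self.alpha_ = best
        self.length_scale_ = float(np.sqrt(1.0 / (2.0 * self.gamma_)))
        self.model_ = KernelRidge(kernel="rbf", gamma=self.gamma_,
                                  alpha=self.alpha_).fit(Xs, ys)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        Xs = self._x_scaler.transform(X)
        return self.model_.predict(Xs) * self._y_std + self._y_mean


@dataclass
class PredictionResult:
    target: str
    predictors: list[str]
    model_kind: str  # "linear" | "se_kernel"
    y_true: np.ndarray = field(repr=False)
    y_pred: np.ndarray = field(repr=False)
    prediction_r: float = 0.0
    folds: int = 5
    seed: int = 0


def _build_model(model_kind: str, seed: int):
    if model_kind == "linear":
        return make_pipeline(StandardScaler(), LinearRegression())
    if model_kind == "se_kernel":
        return SquaredExponentialRegressor(random_state=seed)
    raise ValueError("model_kind must be 'linear' or 'se_kernel'")


def _is_histone_target(target: str) -> bool:
    return "_norm" in target or target.startswith(("H3K", "H4K", "H2A", "H2B"))


def resolve_predictors(features: pd.DataFrame, target: str,
                       predictors: list[str]) -> list[str]:
    """Apply the DAPI exclusion rule for histone targets."""
    missing = [p for p in predictors if p not in features.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")
    if _is_histone_target(target):
        predictors = [p for p in predictors
                      if p not in DAPI_EXCLUDED_PREDICTORS]
    return list(predictors)


def predict(features: pd.DataFrame, target: str, predictors: list[str],
            model_kind: str = "linear", folds: int = 5, seed: int = 0
            ) -> PredictionResult:
    """k-fold cross-validated prediction of ``target`` from ``predictors``.

    All predicted values come from held-out folds; accuracy is the Pearson
    r between predicted and measured values. Requires at least 30 records.
    """
    if target not in features.columns:
        raise KeyError(f"target {target!r} not in table")
    predictors = resolve_predictors(features, target, predictors)
    if not predictors:
        raise ValueError("no predictors remain after exclusions")
    data = features[[target, *predictors]].dropna()
    if len(data) < 30:
        raise ValueError(f"need >= 30 records, got {len(data)}")
    y = data[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant target: prediction undefined")
    X = data[predictors].to_numpy(dtype=float)
    model = _build_model(model_kind, seed)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficiency falls back to lstsq
        y_pred = cross_val_predict(model, X, y, cv=cv)
    yc = y - y.mean()
    pc = y_pred - y_pred.mean()
    denom = np.sqrt((yc ** 2).sum() * (pc ** 2).sum())
    r = float((yc * pc).sum() / denom) if denom > 0 else 0.0
    return PredictionResult(target, predictors, model_kind, y, y_pred, r,
                            folds, seed)


@dataclass
class ImportanceRanking:
    target: str
    model_kind: str
    full_r: float
    table: pd.DataFrame  # columns: feature, delta_r, rank


def dropout_importance(features: pd.DataFrame, target: str,
                       predictors: list[str], model_kind: str = "linear",
                       folds: int = 5, seed: int = 0) -> ImportanceRanking:
    """Single-feature dropout importance.

    Each predictor is removed in turn and the model re-cross-validated on
    the same folds; delta_r = full-model r minus reduced-model r. Ranks are
    by descending delta_r, ties broken by predictor name.
    """
    predictors = resolve_predictors(features, target, predictors)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors for dropout analysis")
    full = predict(features, target, predictors, model_kind, folds, seed)
    rows = []
    for p in predictors:
        reduced = [q for q in predictors if q != p]
        res = predict(features, target, reduced, model_kind, folds, seed)
        rows.append({"feature": p, "delta_r": full.prediction_r - res.prediction_r})
    tab = pd.DataFrame(rows).sort_values(
        ["delta_r", "feature"], ascending=[False, True]).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return ImportanceRanking(target, model_kind, full.prediction_r, tab)


@dataclass
class CCAResult:
    correlations: np.ndarray  # descending canonical correlations
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray = field(repr=False)
    y_scores: np.ndarray = field(repr=False)
    prediction_r: float = 0.0  # first-variate correlation
    ridge: float = 0.0


def cca_predict(cell_features: pd.DataFrame, nucleus_features: pd.DataFrame,
                ridge: float = 0.0) -> CCAResult:
    """Canonical correlation analysis between two feature blocks.

    Classical CCA via SVD of the whitened cross-covariance. Columns are
    z-scored first. A singular within-block covariance triggers automatic
    ridge regularisation (logged via ``warnings``).
    """
    X = np.asarray(cell_features, dtype=float)
    Y = np.asarray(nucleus_features, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("both blocks need >= 2 features")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must share rows")
    n = X.shape[0]
    if n <= max(X.shape[1], Y.shape[1]):
        raise ValueError("need more rows than features")
    X = StandardScaler().fit_transform(X)
    Y = StandardScaler().fit_transform(Y)
    Sxx = X.T @ X / n
    Syy = Y.T @ Y / n
    Sxy = X.T @ Y / n

    def inv_sqrt(S, name):
        nonlocal ridge
        w, V = linalg.eigh(S)
        if w.min() < 1e-10 * w.max():
            add = max(ridge, 1e-8 * w.max())
            if add > ridge:
                warnings.warn(f"singular within-block covariance ({name}); "
                              f"ridge {add:.2e} added")
                ridge = add
            w = w + add
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Wx = inv_sqrt(Sxx, "cell block")
    Wy = inv_sqrt(Syy, "nucleus block")
    U, s, Vt = linalg.svd(Wx @ Sxy @ Wy)
    ncomp = min(X.shape[1], Y.shape[1])
    corrs = np.clip(s[:ncomp], 0.0, 1.0)
    a = Wx @ U[:, :ncomp]
    b = Wy @ Vt.T[:, :ncomp]
    return CCAResult(corrs, a, b, X @ a, Y @ b, float(corrs[0]), ridge)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x components
    scores: np.ndarray = field(repr=False)
    variance_fractions: np.ndarray = field(default=None)
    dropped: list[str] = field(default_factory=list)


def pca_biplot_data(features: pd.DataFrame,
                    include: list[str] | None = None) -> PCAResult:
    """PCA of z-scored features for biplot display.

    Constant features are dropped with a warning; explained-variance
    fractions over all retained components sum to 1.
    """
    cols = list(include) if include is not None else list(features.columns)
    data = features[cols].dropna()
    dropped = [c for c in cols if data[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}")
        cols = [c for c in cols if c not in dropped]
    if len(cols) < 2:
        raise ValueError("need at least 2 non-constant features")
    if len(data) <= len(cols):
        raise ValueError("need more rows than features")
    Z = StandardScaler().fit_transform(data[cols].to_numpy(dtype=float))
    pca = PCA()
    scores = pca.fit_transform(Z)
    loadings = pd.DataFrame(
        pca.components_.T, index=cols,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)])
    return PCAResult(loadings, scores, pca.explained_variance_ratio_, dropped)
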