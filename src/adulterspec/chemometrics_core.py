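"""Shared chemometric engines.

Partial least squares (SIMPLS), seeded k-fold RMSECV, Kennard–Stone sample
partitioning, calibration metrics (R², RMSE, MAE) and Pearson correlation
with a t-test of significance. The PLS engine is a compact univariate-y
SIMPLS written for speed: the wavelength selectors fit tens of thousands of
small PLS sub-models, so per-fit overhead matters more than generality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "SplitResult",
    "MetricSet",
    "CorrelationReport",
    "pls_fit",
    "pls_predict",
    "rmsecv",
    "rmsecv_pls",
    "kfold_indices",
    "kennard_stone_split",
    "compute_metrics",
    "pearson_with_significance",
    "correlation_strength_label",
]


# ---------------------------------------------------------------------------
# PLS (SIMPLS, de Jong 1993), univariate response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSModel:
    coef_: np.ndarray        # (p,) regression vector on original scale
    intercept_: float
    n_components: int        # effective (may be < requested on rank deficiency)
    x_mean_: np.ndarray
    y_mean_: float


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Centered SIMPLS regression of y on X with ``n_components`` latent variables.

    If the deflated covariance collapses before the requested number of
    components (rank deficiency), the model is fitted with the achievable
    number and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, min(n-1, p)] = "
            f"[1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc                      # p-vector: current covariance direction
    R = np.empty((p, n_components))    # weights
    Q = np.empty(n_components)         # y-loadings
    V = np.empty((p, n_components))    # orthonormal basis of X-loadings
    tol = 1e-12 * max(1.0, float(np.abs(s).max(initial=0.0)))
    a = 0
    for a in range(n_components):
        r = s.copy()
        t = Xc @ r
        normt = np.linalg.norm(t)
        if normt <= tol * np.sqrt(n):
            warnings.warn(
                f"rank deficiency: fitted {a} of {n_components} requested "
                f"PLS components", stacklevel=2)
            break
        t /= normt
        r /= normt
        pload = Xc.T @ t
        q = yc @ t
        v = pload.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pload)
        nv = np.linalg.norm(v)
        if nv <= tol:
            warnings.warn(
                f"rank deficiency: fitted {a} of {n_components} requested "
                f"PLS components", stacklevel=2)
            break
        v /= nv
        R[:, a], Q[a], V[:, a] = r, q, v
        s -= v * (v @ s)
    else:
        a = n_components
    if a == 0:
        # X has no usable variance direction: constant model
        return PLSModel(np.zeros(p), float(y_mean), 0, x_mean, float(y_mean))
    coef = R[:, :a] @ Q[:a]
    intercept = y_mean - x_mean @ coef
    return PLSModel(coef, float(intercept), a, x_mean, float(y_mean))


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.coef_ + model.intercept_


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def kfold_indices(n: int, k: int, seed: int) -> list:
    """Contiguous blocks of a seeded shuffle -> list of test-index arrays."""
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def rmsecv(X, y, model_factory, k: int = 10, seed: int = 0) -> float:
    """RMSE over concatenated out-of-fold predictions of a seeded k-fold split.

    ``model_factory()`` must return an estimator with sklearn-style
    ``fit(X, y)`` / ``predict(X)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    resid = np.empty_like(y)
    for test in kfold_indices(len(y), k, seed):
        train = np.setdiff1d(np.arange(len(y)), test)
        est = model_factory()
        est.fit(X[train], y[train])
        resid[test] = y[test] - np.asarray(est.predict(X[test])).ravel()
    return float(np.sqrt(np.mean(resid ** 2)))


def _capped_ncomp(n_train: int, p: int, max_components: int) -> int:
    return max(1, min(max_components, n_train - 1, p))


def rmsecv_pls(X, y, max_components: int = 10, k: int = 10, seed: int = 0) -> float:
    """Fast k-fold RMSECV of a SIMPLS model; the selectors' shared objective.

    The component count per fold is min(max_components, p, n_train−1): a
    deterministic cap rather than a nested search, so every subset evaluated
    anywhere in a selector run is scored by exactly the same rule and fold
    assignment (same seed ⇒ same folds).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    resid = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficient folds are expected
        for test in kfold_indices(n, k, seed):
            train = np.setdiff1d(np.arange(n), test)
            m = pls_fit(X[train], y[train],
                        _capped_ncomp(len(train), p, max_components))
            resid[test] = y[test] - pls_predict(m, X[test])
    return float(np.sqrt(np.mean(resid ** 2)))


# ---------------------------------------------------------------------------
# Kennard–Stone partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray


def kennard_stone_split(X: np.ndarray, calibration_ratio: float = 2 / 3) -> SplitResult:
    """Classic Kennard–Stone max-min selection of a calibration subset.

    Seeds with the two most distant samples (Euclidean), then repeatedly adds
    the sample whose minimum distance to the already-selected set is largest,
    until round(ratio·n) samples are selected (banker's rounding; 64 samples
    at 2:1 gives 43/21). Ties break to the lowest row index. Deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 samples")
    n_cal = int(round(calibration_ratio * n))
    n_cal = max(2, min(n, n_cal))

    sq = np.sum(X ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    # most distant pair, ties to lowest (i, j)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    first = (min(i, j), max(i, j))
    selected = [first[0], first[1]]
    mind2 = np.minimum(d2[first[0]], d2[first[1]])
    mind2[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(mind2))  # argmax takes the first maximum -> lowest index
        selected.append(nxt)
        mind2 = np.minimum(mind2, d2[nxt])
        mind2[nxt] = -np.inf
    cal = np.sort(np.asarray(selected))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred)


# ---------------------------------------------------------------------------
# Metrics and correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float
    mae: float


def compute_metrics(y, y_hat) -> MetricSet:
    """R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE and MAE of predicted vs true content."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: y is constant")
    err = y - y_hat
    return MetricSet(r2=1.0 - float(np.sum(err ** 2)) / ss_tot,
                     rmse=float(np.sqrt(np.mean(err ** 2))),
                     mae=float(np.mean(np.abs(err))))


# |R| thresholds for the qualitative strength labels
_STRENGTH_BINS = ((0.8, "very strong"), (0.7, "strong"), (0.4, "moderate"))


def correlation_strength_label(r: float) -> str:
    a = abs(r)
    for cut, label in _STRENGTH_BINS:
        if a >= cut:
            return label
    return "weak"


@dataclass(frozen=True)
class CorrelationReport:
    wavelength: float
    pearson_r: float
    p_value: float
    strength_label: str


def pearson_with_significance(x, y, wavelength: float = float("nan")) -> CorrelationReport:
    """Pearson R between absorbance and adulteration content with a two-sided
    t-test (t = R·sqrt((n−2)/(1−R²)) on n−2 df) and a qualitative label:
    |R| ≥ 0.8 very strong, ≥ 0.7 strong, ≥ 0.4 moderate, else weak."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationReport(float(wavelength), r, p, correlation_strength_label(r))
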