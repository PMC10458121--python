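"""Feature-wavelength selection: CARS, SPA, BOSS and IVSO.

All four selectors reduce the 2068-wavelength spectrum to a small informative
subset before regression. CARS, BOSS and IVSO are model-population methods
built on a shared PLS/RMSECV core (:func:`adulterspec.chemometrics_core.rmsecv_pls`);
SPA is a collinearity-minimising projection chain scored by multiple linear
regression on a held-out validation split.

Every selector returns a :class:`SelectionResult` carrying the chosen
wavelength indices, the per-iteration RMSECV trace, and the seed, and is
fully deterministic given that seed. Ties everywhere break to the lowest
wavelength index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .chemometrics_core import (kennard_stone_split, pls_fit, rmsecv_pls)
from .spectra_core import WavelengthGrid

__all__ = [
    "SelectionResult",
    "cars_edf_schedule",
    "cars_select",
    "spa_select",
    "boss_select",
    "ivso_select",
    "selection_summary",
]


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected_indices: np.ndarray   # ordered, unique, into the wavelength grid
    rmsecv_trace: np.ndarray       # one RMSECV per iteration
    n_iterations: int
    seed: int

    def __post_init__(self):
        idx = np.asarray(self.selected_indices, dtype=int)
        object.__setattr__(self, "selected_indices", idx)
        object.__setattr__(self, "rmsecv_trace",
                           np.asarray(self.rmsecv_trace, dtype=float))
        if idx.size < 1 or len(np.unique(idx)) != idx.size:
            raise ValueError("selected indices must be non-empty and unique")
        if self.rmsecv_trace.size < 1:
            raise ValueError("rmsecv_trace must be non-empty")

    @property
    def best_rmsecv(self) -> float:
        return float(np.min(self.rmsecv_trace))

    def to_dict(self, grid: WavelengthGrid = None) -> dict:
        d = {"method": self.method,
             "selected_indices": self.selected_indices.tolist(),
             "rmsecv_trace": self.rmsecv_trace.tolist(),
             "n_iterations": int(self.n_iterations),
             "seed": int(self.seed)}
        if grid is not None:
            d["wavelengths_nm"] = grid.values[self.selected_indices].tolist()
        return d


def _normalized_abs_coef(coef: np.ndarray) -> np.ndarray:
    a = np.abs(coef)
    s = a.sum()
    return a / s if s > 0 else a


def _fit_coef(X, y, max_components):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = pls_fit(X, y, max(1, min(max_components, X.shape[0] - 1, X.shape[1])))
    return m.coef_


# ---------------------------------------------------------------------------
# CARS — competitive adaptive reweighted sampling
# ---------------------------------------------------------------------------

def cars_edf_schedule(p: int, n_mc: int) -> np.ndarray:
    """Exponentially decreasing retained-variable counts r_i = a·exp(−k·i),
    fixed by the boundary conditions r_1 = p (all variables) and r_{n_mc} = 2:
    a = p·(p/2)^{1/(N−1)}, k = ln(p/2)/(N−1)."""
    if n_mc < 2 or p < 2:
        raise ValueError("need n_mc >= 2 Monte Carlo runs and p >= 2 variables")
    N = n_mc
    a = p * (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    return np.rint(a * np.exp(-k * i)).astype(int)


def cars_select(X, y, n_mc: int = 100, calib_frac: float = 0.8,
                max_components: int = 10, k: int = 10, seed: int = 0) -> SelectionResult:
    """CARS: per Monte-Carlo run, fit PLS on a random calibration subset, keep
    the top-|coefficient| variables under an exponentially decreasing count
    schedule, resample them by adaptive reweighted sampling (probability ∝
    |coefficient|), and score the survivors by 10-fold RMSECV on the full
    sample set. Returns the run subset with minimal RMSECV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    schedule = cars_edf_schedule(p, n_mc)
    n_cal = max(2, int(round(calib_frac * n)))

    current = np.arange(p)
    traces, subsets = [], []
    for i in range(n_mc):
        cal = np.sort(rng.choice(n, size=n_cal, replace=False))
        b = np.abs(_fit_coef(X[np.ix_(cal, current)], y[cal], max_components))
        r_i = min(int(schedule[i]), current.size)
        # enforced shrink: keep top r_i by |b|; stable sort -> lowest index ties
        order = np.argsort(-b, kind="stable")[:r_i]
        kept = current[np.sort(order)]
        b_kept = b[np.sort(order)]
        # adaptive reweighted sampling among the kept variables
        prob = b_kept / b_kept.sum() if b_kept.sum() > 0 else None
        drawn = rng.choice(kept.size, size=r_i, replace=True, p=prob)
        survivors = kept[np.unique(drawn)]
        if survivors.size < 2:
            break
        current = survivors
        traces.append(rmsecv_pls(X[:, current], y, max_components, k, seed))
        subsets.append(current)
    if not subsets:
        raise RuntimeError("CARS collapsed below 2 variables before any scoring")
    best = int(np.argmin(traces))
    return SelectionResult("cars", subsets[best], np.asarray(traces),
                           len(traces), seed)


# ---------------------------------------------------------------------------
# SPA — successive projections algorithm
# ---------------------------------------------------------------------------

def spa_chain(Xcal: np.ndarray, start: int, max_vars: int) -> np.ndarray:
    """Projection chain from one starting column: repeatedly append the column
    with maximal norm after projection onto the orthogonal complement of the
    span of the chosen columns. Stops early on collinear exhaustion."""
    R = np.asarray(Xcal, dtype=float).copy()
    R = R - R.mean(axis=0)
    n, p = R.shape
    tol = 1e-10 * max(1.0, float(np.linalg.norm(R) / np.sqrt(p)))
    chain = [start]
    for _ in range(min(max_vars, p) - 1):
        u = R[:, chain[-1]]
        nu = np.linalg.norm(u)
        if nu <= tol:
            break
        u = u / nu
        R = R - np.outer(u, u @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol:
            break
        chain.append(nxt)
    return np.asarray(chain, dtype=int)


def _mlr_val_rmse(Xcal, ycal, Xval, yval, cols) -> float:
    A = np.column_stack([np.ones(len(ycal)), Xcal[:, cols]])
    beta, *_ = np.linalg.lstsq(A, ycal, rcond=None)
    pred = np.column_stack([np.ones(len(yval)), Xval[:, cols]]) @ beta
    return float(np.sqrt(np.mean((yval - pred) ** 2)))


def spa_select(X, y, min_vars: int = 1, max_vars: int = 40,
               seed: int = 0, calibration_ratio: float = 2 / 3) -> SelectionResult:
    """SPA: for every starting wavelength, build the minimal-collinearity
    projection chain, then score every chain prefix of length min_vars..max_vars
    by the validation RMSE of a multiple linear regression (Kennard–Stone
    calibration/validation split). Returns the best (start, length) prefix.

    Deterministic; ``seed`` is recorded for interface uniformity only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= min_vars <= max_vars:
        raise ValueError("need 1 <= min_vars <= max_vars")
    if max_vars > min(n - 1, p):
        raise ValueError(f"max_vars={max_vars} exceeds min(n-1, p)={min(n - 1, p)}")
    split = kennard_stone_split(X, calibration_ratio)
    cal, val = split.calibration_indices, split.prediction_indices
    Xcal, ycal, Xval, yval = X[cal], y[cal], X[val], y[val]

    best = (np.inf, None)   # (rmse, prefix)
    trace = np.empty(p)
    for start in range(p):
        chain = spa_chain(Xcal, start, max_vars)
        start_best = np.inf
        for m in range(min_vars, len(chain) + 1):
            r = _mlr_val_rmse(Xcal, ycal, Xval, yval, chain[:m])
            if r < start_best:
                start_best = r
            if r < best[0]:
                best = (r, np.sort(chain[:m]))
        trace[start] = start_best
    return SelectionResult("spa", best[1], trace, p, seed)


# ---------------------------------------------------------------------------
# BOSS — bootstrapping soft shrinkage
# ---------------------------------------------------------------------------

def boss_select(X, y, n_boot: int = 1000, submodel_frac_best: float = 0.1,
                max_components: int = 10, k: int = 10, seed: int = 0,
                max_iterations: int = 50) -> SelectionResult:
    """BOSS: weighted bootstrap sampling of variable subsets, PLS sub-models
    scored by RMSECV, and soft shrinkage — each variable's new weight is the
    sum of its normalised |PLS coefficient| over the best fraction of
    sub-models. Zero-weight variables drop out; iteration stops when the
    variable pool stops shrinking. Returns the pool with minimal RMSECV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    rng = np.random.default_rng(seed)
    n_best = max(1, int(round(submodel_frac_best * n_boot)))

    pool = np.arange(p)
    weights = np.full(p, 1.0 / p)
    traces, pools = [], []
    no_shrink = 0
    for _ in range(max_iterations):
        traces.append(rmsecv_pls(X[:, pool], y, max_components, k, seed))
        pools.append(pool)
        if pool.size <= 2:
            break
        w = weights[pool] / weights[pool].sum()
        scores = np.empty(n_boot)
        subs, coefs = [], []
        for b in range(n_boot):
            drawn = rng.choice(pool.size, size=pool.size, replace=True, p=w)
            sub = np.unique(drawn)          # positions within pool
            cols = pool[sub]
            scores[b] = rmsecv_pls(X[:, cols], y, max_components, k, seed)
            subs.append(sub)
            coefs.append(_normalized_abs_coef(
                _fit_coef(X[:, cols], y, max_components)))
        best_rows = np.argsort(scores, kind="stable")[:n_best]
        new_w = np.zeros(p)
        for b in best_rows:
            np.add.at(new_w, pool[subs[b]], coefs[b])
        total = new_w.sum()
        if total <= 0:
            raise RuntimeError("degenerate shrinkage: all variable weights zero")
        weights = new_w / total
        new_pool = np.flatnonzero(weights > 0)
        if new_pool.size >= pool.size:
            # elimination can lag one round while the weights skew; stop only
            # when two consecutive updates fail to shrink the pool
            no_shrink += 1
            if no_shrink >= 2:
                break
        else:
            no_shrink = 0
            pool = new_pool
    best = int(np.argmin(traces))
    return SelectionResult("boss", pools[best], np.asarray(traces),
                           len(traces), seed)


# ---------------------------------------------------------------------------
# IVSO — iteratively variable subset optimization
# ---------------------------------------------------------------------------

def ivso_select(X, y, n_wbms: int = 1000, submodel_frac_best: float = 0.1,
                max_components: int = 10, k: int = 10, seed: int = 0,
                max_iterations: int = 50) -> SelectionResult:
    """IVSO: weighted binary matrix sampling (each sub-model includes variable
    v with probability w_v, initially 0.5), PLS sub-models scored by RMSECV,
    variable weights accumulated from the best sub-models, then sequential
    addition — nested prefixes of the weight ranking are evaluated and the
    best prefix becomes the next pool. Stops when the pool stops shrinking;
    returns the subset with the global minimum RMSECV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_wbms < 10:
        raise ValueError("n_wbms must be >= 10")
    rng = np.random.default_rng(seed)
    n_best = max(1, int(round(submodel_frac_best * n_wbms)))

    pool = np.arange(p)
    w = np.full(p, 0.5)
    traces, subsets = [], []
    for _ in range(max_iterations):
        M = rng.random((n_wbms, pool.size)) < w
        scores = np.empty(n_wbms)
        coefs = []
        for b in range(n_wbms):
            sub = np.flatnonzero(M[b])
            if sub.size < 2:   # degenerate row: force the two heaviest variables
                sub = np.argsort(-w, kind="stable")[:2]
                M[b, :] = False
                M[b, sub] = True
            cols = pool[sub]
            scores[b] = rmsecv_pls(X[:, cols], y, max_components, k, seed)
            coefs.append(_normalized_abs_coef(
                _fit_coef(X[:, cols], y, max_components)))
        best_rows = np.argsort(scores, kind="stable")[:n_best]
        weight = np.zeros(pool.size)
        for b in best_rows:
            np.add.at(weight, np.flatnonzero(M[b]), coefs[b])
        if weight.sum() <= 0:
            raise RuntimeError("empty coefficient mass in best WBMS rows")
        # sequential addition over nested prefixes of the weight ranking
        order = np.argsort(-weight, kind="stable")
        prefix_scores = np.empty(pool.size)
        for m in range(1, pool.size + 1):
            cols = np.sort(pool[order[:m]])
            prefix_scores[m - 1] = rmsecv_pls(X[:, cols], y, max_components,
                                              k, seed)
        best_m = int(np.argmin(prefix_scores)) + 1
        traces.append(float(prefix_scores[best_m - 1]))
        new_pool = np.sort(pool[order[:best_m]])
        subsets.append(new_pool)
        if new_pool.size >= pool.size:
            break
        # rescale weights to the surviving pool (max weight -> probability 1)
        kept_w = weight[order[:best_m]]
        w = kept_w[np.argsort(pool[order[:best_m]], kind="stable")]
        w = w / w.max()
        pool = new_pool
    best = int(np.argmin(traces))
    return SelectionResult("ivso", subsets[best], np.asarray(traces),
                           len(traces), seed)


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def _percent_half_up(count: int, total: int) -> float:
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def selection_summary(results: list, grid: WavelengthGrid) -> pd.DataFrame:
    """Per-method counts, percent of the full grid (2 decimals, half-up) and a
    histogram over the UV (<400 nm), Vis (400-780 nm) and NIR (>780 nm) bands."""
    if not results:
        raise ValueError("no selection results to summarise")
    uv, vis, nir = grid.band_masks()
    rows = []
    for res in results:
        sel = np.zeros(len(grid), dtype=bool)
        sel[res.selected_indices] = True
        rows.append({
            "method": res.method,
            "n_selected": int(res.selected_indices.size),
            "percent_of_spectrum": _percent_half_up(res.selected_indices.size,
                                                    len(grid)),
            "n_uv": int(np.sum(sel & uv)),
            "n_vis": int(np.sum(sel & vis)),
            "n_nir": int(np.sum(sel & nir)),
            "best_rmsecv": res.best_rmsecv,
        })
    return pd.DataFrame(rows)
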