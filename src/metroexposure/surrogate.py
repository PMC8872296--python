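"""Measurement-fusion surrogates: K-means partition, epsilon-SVR, PSO tuning.

Each region (A-type and B-type on the concourse, the whole platform) gets an
RBF-kernel epsilon-insensitive support vector regression mapping the
per-state simulated concentrations at a point to the measured concentration
there.  The SVR convention follows

    min  1/2 ||w||^2 + lambda * sum(xi + xi*)     (tube half-width epsilon)
    kernel  k(x, x') = exp(-sigma ||x - x'||^2)

so ``lambda`` plays the role of scikit-learn's C and ``sigma`` of gamma;
inputs are standardized inside the model.  The two hyper-parameters are tuned
by a global-best particle swarm maximizing 5-fold cross-validated R^2 on the
training set; the test split is held out strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.svm import SVR

from .station import CONCOURSE, Grid2D
from .synthesis import STATE_COLUMNS


def input_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in STATE_COLUMNS.values() if c in table.columns]


def r_squared(measured, predicted) -> float:
    """Coefficient of determination 1 - SSres/SStot (may be negative)."""
    y = np.asarray(measured, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length arrays with at least 2 points")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("zero total variance: R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


# ---------------------------------------------------------------------------
# clustering and splits

def kmeans_partition(table: pd.DataFrame, k: int = 2, seed: int = 0,
                     n_init: int = 10) -> np.ndarray:
    """K-means labels on standardized (inputs, measured) features."""
    if k < 2:
        raise ValueError("k must be >= 2")
    feats = table[input_columns(table) + ["measured"]].to_numpy(float)
    if len(feats) < k:
        raise ValueError("fewer rows than clusters")
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    # tiny tables get many restarts so Lloyd's reliably reaches the global
    # within-cluster-sum-of-squares optimum
    n_init = max(n_init, 200) if len(feats) <= 16 else n_init
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(z)


def ab_labels(table: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """Map the 2-cluster partition to A (interior / supply-influenced) and
    B (exit-proximal / outdoor-influenced) types.

    The cluster holding the larger share of passageway points is B; ties
    break on the higher mean open-state simulated value.
    """
    is_pass = table.zone.str.startswith("passageway").to_numpy()
    out = np.empty(len(labels), dtype="<U1")
    frac = [is_pass[labels == c].mean() if np.any(labels == c) else 0.0
            for c in (0, 1)]
    if frac[0] == frac[1]:
        open_col = "sim_open" if "sim_open" in table.columns else \
            input_columns(table)[-1]
        frac = [table[open_col][labels == c].mean() for c in (0, 1)]
    b_cluster = int(np.argmax(frac))
    out[labels == b_cluster] = "B"
    out[labels != b_cluster] = "A"
    return out


def split_train_test(table: pd.DataFrame, n_test: int, seed: int = 0):
    """Uniform random train/test split without replacement."""
    n = len(table)
    if not 0 < n_test < n:
        raise ValueError("n_test must satisfy 0 < n_test < n")
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    mask = np.zeros(n, bool)
    mask[test_idx] = True
    return (table[~mask].reset_index(drop=True),
            table[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# SVR

@dataclass
class SurrogateModel:
    """Fitted region surrogate f(x) = sum_i alpha_i k(x_i, x) + b."""

    region: str
    lam: float
    sigma: float
    epsilon: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    support_vectors: np.ndarray  # standardized coordinates
    dual_coef: np.ndarray
    intercept: float
    d: int
    meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.d:
            raise ValueError(
                f"expected {self.d} inputs for region {self.region}, "
                f"got {X.shape[1]}")
        Z = (X - self.x_mean) / self.x_scale
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.sigma * d2) @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "region": self.region, "lam": self.lam, "sigma": self.sigma,
            "epsilon": self.epsilon, "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept, "d": self.d, "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, dd: dict) -> "SurrogateModel":
        return cls(
            region=dd["region"], lam=dd["lam"], sigma=dd["sigma"],
            epsilon=dd["epsilon"], x_mean=np.asarray(dd["x_mean"]),
            x_scale=np.asarray(dd["x_scale"]),
            support_vectors=np.asarray(dd["support_vectors"]),
            dual_coef=np.asarray(dd["dual_coef"]),
            intercept=dd["intercept"], d=dd["d"], meta=dict(dd.get("meta", {})),
        )


def train_svr(train_inputs, train_outputs, lam: float, sigma: float,
              epsilon: float = 0.1, region: str = "", tol: float = 1e-7,
              meta: dict | None = None) -> SurrogateModel:
    """Fit the epsilon-insensitive RBF SVR (inputs standardized internally)."""
    if lam <= 0 or sigma <= 0 or epsilon < 0:
        raise ValueError("require lam > 0, sigma > 0, epsilon >= 0")
    X = np.atleast_2d(np.asarray(train_inputs, float))
    y = np.asarray(train_outputs, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    svr = SVR(kernel="rbf", C=lam, gamma=sigma, epsilon=epsilon, tol=tol,
              max_iter=10_000_000)
    svr.fit(Z, y)
    if svr.fit_status_ != 0:  # pragma: no cover
        raise RuntimeError("SVR solver did not converge")
    return SurrogateModel(
        region=region, lam=lam, sigma=sigma, epsilon=epsilon,
        x_mean=mu, x_scale=sd,
        support_vectors=svr.support_vectors_.copy(),
        dual_coef=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]), d=X.shape[1],
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# PSO hyper-parameter tuning

@dataclass
class PSOResult:
    lam: float
    sigma: float
    score: float
    history: list  # best validation score after each iteration


def _cv_r2(X, y, lam, sigma, epsilon, n_folds, fold_seeds) -> float:
    """Mean R^2 over repeated k-fold cross-validation (one repeat per seed)."""
    n = len(y)
    scores = []
    for fs in fold_seeds:
        rng = np.random.default_rng(fs)
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        preds = np.empty(n)
        for fold in folds:
            mask = np.zeros(n, bool)
            mask[fold] = True
            m = train_svr(X[~mask], y[~mask], lam, sigma, epsilon)
            preds[mask] = m.predict(X[mask])
        scores.append(r_squared(y, preds))
    return float(np.mean(scores))


def pso_tune(train_inputs, train_outputs,
             bounds_log_lambda=(-2.0, 4.0), bounds_log_sigma=(-3.0, 2.0),
             swarm: int = 12, iters: int = 20, seed: int = 0,
             epsilon: float = 0.1, n_folds: int = 5, n_repeats: int = 3,
             inertia: float = 0.7, c1: float = 1.5, c2: float = 1.5
             ) -> PSOResult:
    """Global-best PSO over (log10 lambda, log10 sigma).

    The objective is repeated 5-fold cross-validated R^2 on the training set
    (``n_repeats`` fold shuffles averaged, which damps fold-assignment luck);
    the best score is non-decreasing across iterations by construction.
    """
    lo = np.array([bounds_log_lambda[0], bounds_log_sigma[0]], float)
    hi = np.array([bounds_log_lambda[1], bounds_log_sigma[1]], float)
    if np.any(hi <= lo):
        raise ValueError("degenerate hyper-parameter bounds")
    if swarm < 1:
        raise ValueError("swarm must be >= 1")
    X = np.atleast_2d(np.asarray(train_inputs, float))
    y = np.asarray(train_outputs, float)
    n_folds = min(n_folds, len(y))
    rng = np.random.default_rng(seed)
    fold_seeds = [int(rng.integers(2 ** 31 - 1)) for _ in range(n_repeats)]

    def objective(p):
        return _cv_r2(X, y, 10.0 ** p[0], 10.0 ** p[1], epsilon,
                      n_folds, fold_seeds)

    pos = lo + rng.random((swarm, 2)) * (hi - lo)
    vel = np.zeros((swarm, 2))
    pbest = pos.copy()
    pscore = np.array([objective(p) for p in pos])
    g = int(np.argmax(pscore))
    gbest, gscore = pbest[g].copy(), float(pscore[g])
    history = [gscore]
    vmax = 0.5 * (hi - lo)
    for _ in range(iters):
        r1 = rng.random((swarm, 2))
        r2 = rng.random((swarm, 2))
        vel = (inertia * vel + c1 * r1 * (pbest - pos)
               + c2 * r2 * (gbest - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for k in range(swarm):
            s = objective(pos[k])
            if s > pscore[k]:
                pscore[k] = s
                pbest[k] = pos[k]
                if s > gscore:
                    gscore, gbest = float(s), pos[k].copy()
        history.append(gscore)
    return PSOResult(lam=float(10.0 ** gbest[0]),
                     sigma=float(10.0 ** gbest[1]),
                     score=gscore, history=history)


# ---------------------------------------------------------------------------
# region routing

@dataclass
class RegionMap:
    """Per-cell surrogate-region label for one floor grid."""

    grid: Grid2D
    labels: np.ndarray  # (n_rows, n_cols) of region names

    def region_at(self, x, y):
        i, j = self.grid.cell_of(x, y)
        return self.labels[i, j]


def build_region_map(grid: Grid2D, points_xy: np.ndarray,
                     point_labels: np.ndarray) -> RegionMap:
    """Voronoi (nearest labeled sample point) region assignment."""
    pts = np.asarray(points_xy, float)
    if len(pts) == 0:
        raise ValueError("no labeled points")
    cx, cy = grid.cell_centers()
    tree = cKDTree(pts)
    _, nearest = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
    labels = np.asarray(point_labels)[nearest].reshape(grid.shape)
    return RegionMap(grid=grid, labels=labels)


def platform_region_map(grid: Grid2D) -> RegionMap:
    return RegionMap(grid=grid,
                     labels=np.full(grid.shape, "platform", dtype="<U8"))


def predict_concentration(bank: dict, region_map: RegionMap, location,
                          sim_values) -> float:
    """Route a location's simulated state values to its region's surrogate."""
    x, y = location
    region = str(region_map.region_at(x, y))
    model = bank[region]
    pred = model.predict(np.atleast_2d(sim_values))
    return float(np.maximum(pred, 0.0)[0])
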