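"""Chemometric core: autoscaling, SPXY partitioning, NIPALS PLS, metrics.

These are the calibration-transfer building blocks common in chemometrics,
applied here to daily agro-meteorological feature matrices:

* **autoscale** — column-wise standardisation to zero mean, unit sample
  standard deviation (ddof = 1), with stored parameters for inversion.
* **SPXY** — sample-set partitioning based on joint x–y distances: a
  deterministic max–min selection that spreads calibration (model-set)
  samples over both predictor and response space.
* **PLS1 (NIPALS)** — sequential extraction of covariance-maximising latent
  vectors with X-deflation, folded into a single regression vector.
* **validation metrics** — RMSEC/RMSECV, SEP, bias, RPD and r, the standard
  suite for judging a calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy import stats

__all__ = [
    "ScalingParams",
    "autoscale",
    "apply_scaling",
    "inverse_scale",
    "Partition",
    "spxy_partition",
    "PLSFit",
    "fit_pls",
    "cross_validate",
    "ModelMetrics",
    "compute_metrics",
]


# ---------------------------------------------------------------------------
# autoscaling

@dataclass(frozen=True)
class ScalingParams:
    """Column means and sample standard deviations used for autoscaling."""

    mean: np.ndarray
    std: np.ndarray
    columns: tuple[str, ...] | None = None


def autoscale(X: np.ndarray, columns: tuple[str, ...] | None = None):
    """Standardise columns to zero mean, unit sample sd (ddof=1).

    Returns ``(X_scaled, ScalingParams)``.  A constant column cannot be
    scaled and raises an error naming it.
    """
    X = np.asarray(X, dtype=float)
    two_d = X.ndim == 2
    Xm = X if two_d else X[:, None]
    mean = Xm.mean(axis=0)
    std = Xm.std(axis=0, ddof=1)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        names = [columns[i] if columns else f"column {i}" for i in bad]
        raise ValueError(f"constant column(s), cannot autoscale: {names}")
    scaled = (Xm - mean) / std
    params = ScalingParams(mean, std, columns)
    return (scaled if two_d else scaled[:, 0]), params


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.mean) / params.std


def inverse_scale(X_scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    X_scaled = np.asarray(X_scaled, dtype=float)
    return X_scaled * params.std + params.mean


# ---------------------------------------------------------------------------
# SPXY partitioning

@dataclass(frozen=True)
class Partition:
    """Model-set / test-set row split."""

    model_set: np.ndarray
    test_set: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_set", np.asarray(self.model_set, dtype=int))
        object.__setattr__(self, "test_set", np.asarray(self.test_set, dtype=int))


def spxy_partition(X: np.ndarray, y: np.ndarray, fraction: float = 0.8) -> Partition:
    """SPXY max–min selection of the model set.

    Joint distance ``d(i,j) = dx(i,j)/max(dx) + dy(i,j)/max(dy)`` (Euclidean
    in x, absolute difference in y).  The two samples attaining the maximum
    joint distance seed the model set; samples are then added greedily, each
    time taking the one whose minimum joint distance to the current model set
    is largest, until ``round(fraction · n)`` samples are selected.  Fully
    deterministic; ties break toward the lowest row index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    dx = cdist(X, X)
    dy = cdist(y, y)
    if dx.max() == 0 or dy.max() == 0:
        raise ValueError("degenerate data: zero spread in x or y space")
    d = dx / dx.max() + dy / dy.max()

    n_ms = int(round(fraction * n))
    n_ms = max(n_ms, 2)
    # seed: the pair with maximum joint distance (lowest indices on ties)
    flat = np.argmax(d)
    i, j = np.unravel_index(flat, d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < n_ms and remaining:
        min_d = d[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]  # argmax returns first (lowest index) on ties
        selected.append(pick)
        remaining.remove(pick)
    return Partition(np.sort(selected), np.array(sorted(remaining), dtype=int), fraction)


# ---------------------------------------------------------------------------
# PLS1 via NIPALS

@dataclass(frozen=True)
class PLSFit:
    """Latent-vector decomposition and folded regression vector (scaled space)."""

    n_lv: int
    weights: np.ndarray       # W, (p, a)
    x_loadings: np.ndarray    # P, (p, a)
    y_loadings: np.ndarray    # q, (a,)
    scores: np.ndarray        # T, (n, a)
    coef: np.ndarray          # (p,), y_scaled ≈ X_scaled @ coef
    explained_x_variance: np.ndarray  # fraction of X variance per LV

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) @ self.coef


def fit_pls(X_scaled: np.ndarray, y_scaled: np.ndarray, n_lv: int) -> PLSFit:
    """Fit a univariate-response PLS model by NIPALS.

    Per latent vector: the weight is the direction of covariance between the
    deflated X and y residuals, the score its projection, followed by rank-one
    deflation of X.  With ``n_lv = rank(X)`` the folded coefficients reproduce
    the least-squares solution.
    """
    X = np.array(X_scaled, dtype=float)
    y = np.array(y_scaled, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite entries in X or y")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}], got {n_lv}")

    total_ssx = (X ** 2).sum()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    evx = np.zeros(n_lv)
    Xr, yr = X.copy(), y.copy()
    for a in range(n_lv):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual covariance exhausted; keep remaining LVs as zeros
            W, P, T = W[:, : a], P[:, : a], T[:, : a]
            q, evx = q[:a], evx[:a]
            n_lv = a
            break
        w /= norm
        t = Xr @ w
        tt = t @ t
        pl = Xr.T @ t / tt
        qa = yr @ t / tt
        Xr -= np.outer(t, pl)
        yr -= qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, qa, t
        evx[a] = tt * (pl @ pl) / total_ssx if total_ssx > 0 else 0.0
    if n_lv == 0:
        raise ValueError("y has no covariance with X; nothing to fit")
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSFit(n_lv, W, P, q, T, coef, evx)


# ---------------------------------------------------------------------------
# cross-validation

def _loo_folds(n: int):
    for i in range(n):
        yield np.array([i]), np.concatenate([np.arange(i), np.arange(i + 1, n)])


def _block_folds(n: int, k: int):
    bounds = np.linspace(0, n, k + 1).astype(int)
    for b in range(k):
        held = np.arange(bounds[b], bounds[b + 1])
        yield held, np.setdiff1d(np.arange(n), held)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    scheme: str = "loo",
    n_blocks: int = 5,
) -> np.ndarray:
    """RMSECV (raw response units) for each latent-vector count 1..max_lv.

    Scaling is re-estimated inside every training fold; held-out predictions
    are back-transformed before the error is pooled.  ``scheme`` is ``"loo"``
    (leave-one-out) or ``"blocks"`` (``n_blocks`` contiguous blocks, suited to
    temporally ordered rows).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if scheme == "loo":
        folds = list(_loo_folds(n))
    elif scheme == "blocks":
        folds = list(_block_folds(n, n_blocks))
    else:
        raise ValueError(f"unknown cv scheme {scheme!r}")
    sq_err = np.zeros(max_lv)
    counts = np.zeros(max_lv)
    for held, train in folds:
        try:
            Xs, xp = autoscale(X[train])
            ys, yp = autoscale(y[train])
        except ValueError:
            import warnings

            warnings.warn("skipping CV fold with a constant column")
            continue
        fold_max = min(max_lv, min(train.size - 1, X.shape[1]))
        for a in range(1, fold_max + 1):
            fit = fit_pls(Xs, ys, a)
            pred = inverse_scale(fit.predict(apply_scaling(X[held], xp)), yp)
            sq_err[a - 1] += ((pred - y[held]) ** 2).sum()
            counts[a - 1] += held.size
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(sq_err / counts)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ModelMetrics:
    """Chemometric validation metrics for one prediction set."""

    rmse: float
    sep: float
    bias: float
    r: float
    rpd: float        # reference sd / rmse; inf when rmse == 0
    n: int

    @property
    def rpd_is_infinite(self) -> bool:
        return not np.isfinite(self.rpd)


def compute_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    reference_sd: float | None = None,
) -> ModelMetrics:
    """RMSE, SEP, bias, Pearson r and RPD of predictions against observations.

    * bias = mean(pred − obs)
    * RMSE = sqrt(mean((pred − obs)²))
    * SEP  = sqrt(Σ(pred − obs − bias)² / (n − 1))  (bias-corrected)
    * RPD  = reference sd / RMSE (infinite flag when RMSE = 0); the reference
      sd defaults to the sample sd of the observed values.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    e = pred - obs
    n = obs.size
    bias = float(e.mean())
    rmse = float(np.sqrt((e ** 2).mean()))
    sep = float(np.sqrt(((e - bias) ** 2).sum() / (n - 1)))
    if reference_sd is None:
        reference_sd = float(obs.std(ddof=1))
    rpd = float(reference_sd / rmse) if rmse > 0 else float("inf")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(obs, pred)[0])
    return ModelMetrics(rmse=rmse, sep=sep, bias=bias, r=r, rpd=rpd, n=n)
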