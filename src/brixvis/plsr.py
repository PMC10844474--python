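"""Partial least squares regression (single response, NIPALS) with
cross-validated latent-variable selection and the evaluation metrics used
throughout the pipeline.

The ``R`` statistic is computed in two modes because the literature is
ambiguous about whether the printed "correlation coefficient" is
``1 - SSres/SStot`` or its square root; ``mode="paper"`` is the former
(the formula as printed), ``mode="sqrt"`` its square root clipped at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Dataset:
    """n x p predictor matrix with paired response and wavelength axis."""

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match X rows")
        if self.wavelengths.shape != (self.X.shape[1],):
            raise ValueError("wavelengths length must match X columns")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.X.shape[0])]
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class PLSRModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # p x n_lv (unit-norm columns)
    x_loadings: np.ndarray  # p x n_lv
    y_loadings: np.ndarray  # n_lv
    coef: np.ndarray        # p, on centered scale
    tags: tuple = ()

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)


@dataclass
class EvaluationMetrics:
    r: float
    rmse: float
    n: int
    mode: str = "paper"


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """NIPALS PLS1: center, extract ``n_lv`` components, assemble the
    regression vector ``b = W (P'W)^{-1} q``.

    Requesting more components than the data's rank supports stops early
    with a warning and returns the achieved count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.std() == 0:
        raise ValueError("zero-variance response")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    max_rank = min(n - 1, p)
    if n_lv > max_rank:
        warnings.warn(f"n_lv={n_lv} capped at rank bound {max_rank}", stacklevel=2)
        n_lv = max_rank

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(float(np.linalg.norm(Xc.T @ yc)), 1e-300)

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    achieved = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * scale:
            warnings.warn(
                f"rank exhausted after {achieved} latent variables (asked {n_lv})",
                stacklevel=2,
            )
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_load = Xc.T @ t / tt
        q_a = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q_a * t
        W[:, a] = w
        P[:, a] = p_load
        q[a] = q_a
        achieved += 1

    if achieved == 0:
        raise ValueError("no latent variable could be extracted")
    W, P, q = W[:, :achieved], P[:, :achieved], q[:achieved]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(n_lv=achieved, x_mean=x_mean, y_mean=y_mean,
                     weights=W, x_loadings=P, y_loadings=q, coef=coef)


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def compute_metrics(y: np.ndarray, y_hat: np.ndarray, mode: str = "paper") -> EvaluationMetrics:
    """R and RMSE of a prediction against reference values.

    paper mode: ``R = 1 - SSres/SStot``; sqrt mode: ``sqrt(max(R, 0))``.
    ``RMSE = sqrt(mean squared residual)``. The reference mean is taken
    over the evaluated set itself.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance reference values")
    ss_res = float(np.sum((y - y_hat) ** 2))
    r = 1.0 - ss_res / ss_tot
    if mode == "sqrt":
        r = float(np.sqrt(max(r, 0.0)))
    elif mode != "paper":
        raise ValueError("mode must be 'paper' or 'sqrt'")
    return EvaluationMetrics(r=r, rmse=float(np.sqrt(ss_res / n)), n=n, mode=mode)


def save_model(model: PLSRModel, path) -> None:
    """JSON round-trip of the fitted factorization."""
    import json

    payload = {
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "tags": list(model.tags),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PLSRModel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return PLSRModel(
        n_lv=int(d["n_lv"]),
        x_mean=np.array(d["x_mean"]),
        y_mean=float(d["y_mean"]),
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        coef=np.array(d["coef"]),
        tags=tuple(d.get("tags", ())),
    )


def _cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    perm = np.random.default_rng(seed).permutation(n)
    return [perm[i::k] for i in range(k)]


def _fit_nipals_multi(X, y, max_lv):
    """Coefficient vectors for every LV count 1..max_lv in one NIPALS sweep."""
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    achieved = 0
    scale = max(float(np.linalg.norm(Xc.T @ yc)), 1e-300)
    for a in range(max_lv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * scale:
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        P[:, a] = Xc.T @ t / tt
        q[a] = float(yc @ t / tt)
        Xc -= np.outer(t, P[:, a])
        yc -= q[a] * t
        W[:, a] = w
        achieved += 1
    coefs = np.zeros((achieved, p))
    for a in range(1, achieved + 1):
        coefs[a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    return coefs, x_mean, y_mean, achieved


def select_lvs_cv(X: np.ndarray, y: np.ndarray, max_lv: int = 20,
                  k_folds: int = 5, seed: int = 0) -> tuple[int, np.ndarray]:
    """Pick the LV count minimizing pooled k-fold RMSECV (ties -> fewest).

    Returns ``(n_lv, rmsecv_curve)`` where the curve is indexed by LV
    count - 1. Candidates beyond the smallest per-fold rank bound are
    capped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < k_folds:
        raise ValueError("need at least k_folds samples")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    folds = _cv_folds(n, k_folds, seed)
    cap = min(min(n - f.size - 1 for f in folds), X.shape[1])
    if max_lv > cap:
        warnings.warn(f"max_lv={max_lv} capped at per-fold rank bound {cap}", stacklevel=2)
        max_lv = cap

    preds = np.full((max_lv, n), np.nan)
    achieved_min = max_lv
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        coefs, x_mean, y_mean, achieved = _fit_nipals_multi(
            X[mask].copy(), y[mask].copy(), max_lv
        )
        achieved_min = min(achieved_min, achieved)
        Xt = X[test_idx] - x_mean
        for a in range(achieved):
            preds[a, test_idx] = Xt @ coefs[a] + y_mean
    max_lv = achieved_min
    rmsecv = np.sqrt(np.mean((preds[:max_lv] - y[None, :]) ** 2, axis=1))
    best = int(np.argmin(rmsecv)) + 1
    return best, rmsecv
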