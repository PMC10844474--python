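"""Least-angle-regression wavelength selection.

Implements the LARS path with the lasso modification (variables may leave
the active set when their coefficient crosses zero), so the path knots are
exactly the lasso solution path for the objective

    (1 / 2n) * ||y - X b||^2  +  lambda * ||b||_1

on column-standardized predictors. A ridge-flavoured variant runs the same
path on the elastic-net-style augmented design ``[X; sqrt(n*lambda) I]``,
whose unpenalized end equals ridge regression with penalty ``lambda``; a
cross-validated stopping knot then yields a finite variable subset, which
plain ridge on its own would never produce.

Selected wavelength subsets feed a reduced PLSR model; ``scan_lambda``
traces prediction performance across a lambda grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import plsr

logger = logging.getLogger(__name__)

PENALTIES = ("L1", "L2")


class EmptySelectionError(ValueError):
    """No variable is active at the requested regularization strength."""


@dataclass
class Standardization:
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    kept: np.ndarray  # indices of non-constant columns, into the original X


@dataclass
class LarsPath:
    """Piecewise-linear lasso coefficient path.

    ``lambdas`` are strictly decreasing knot penalties (first knot: empty
    active set at lambda_max); ``coefs[k]`` is the coefficient vector at
    knot k on the standardized scale; between knots coefficients are
    linear in lambda.
    """

    lambdas: np.ndarray        # n_knots
    coefs: np.ndarray          # n_knots x p
    active_sets: list[np.ndarray]
    n_samples: int

    @property
    def lambda_max(self) -> float:
        return float(self.lambdas[0])


@dataclass
class SelectionResult:
    lam: float
    penalty: str
    indices: np.ndarray        # 0-based channel indices into the original grid
    wavelengths_nm: np.ndarray
    coefficients: np.ndarray   # original-scale coefficients, aligned to indices
    intercept: float

    @property
    def count(self) -> int:
        return int(self.indices.size)


def standardize_for_path(X: np.ndarray, y: np.ndarray,
                         wavelengths: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray, Standardization]:
    """Center/unit-sample-SD columns and center y; drop constant columns."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    keep = x_sd > 0
    if not keep.any():
        raise ValueError("all candidate columns have zero variance")
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        names = (np.asarray(wavelengths)[dropped] if wavelengths is not None else dropped)
        warnings.warn(f"excluding {dropped.size} constant column(s): {names}", stacklevel=2)
    kept = np.flatnonzero(keep)
    Xs = (X[:, kept] - x_mean[kept]) / x_sd[kept]
    ys = y - y.mean()
    info = Standardization(x_mean=x_mean, x_sd=x_sd, y_mean=float(y.mean()), kept=kept)
    return Xs, ys, info


def lars_path_l1(Xs: np.ndarray, ys: np.ndarray,
                 max_steps: int | None = None,
                 max_active: int | None = None) -> LarsPath:
    """LARS with the lasso modification on standardized inputs.

    At each step the active set moves along its equiangular direction
    until either an inactive variable's correlation catches up (entry) or
    an active coefficient hits zero (drop). Ties on entry break toward
    the lowest column index. The path ends at the least-squares fit, at
    the sample-size limit on the active set, or after ``max_steps``.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if not (np.all(np.isfinite(Xs)) and np.all(np.isfinite(ys))):
        raise ValueError("non-finite inputs")
    n, p = Xs.shape
    limit = min(n - 1, p) if max_active is None else min(max_active, min(n - 1, p))
    if max_steps is None:
        max_steps = 8 * (limit + 1)

    c_scale = max(float(np.abs(Xs.T @ ys).max()), 1e-300)
    tol = 1e-10 * c_scale

    beta = np.zeros(p)
    active: list[int] = []
    is_active = np.zeros(p, dtype=bool)
    lambdas = [0.0]  # placeholder, overwritten below
    coefs = [beta.copy()]
    active_sets = [np.array([], dtype=int)]
    drop_pending = False

    r = ys - Xs @ beta
    c = Xs.T @ r
    C = float(np.abs(c).max())
    lambdas[0] = C / n

    for _ in range(max_steps):
        if C <= tol:
            break
        if not drop_pending:
            if len(active) >= limit:
                break
            # entry: largest absolute correlation among inactive, lowest index on ties
            cand = np.flatnonzero(~is_active)
            if cand.size == 0:
                break
            amax = np.abs(c[cand]).max()
            j = int(cand[np.abs(c[cand]) >= amax - 1e-12 * max(amax, 1.0)][0])
            active.append(j)
            is_active[j] = True
        drop_pending = False

        A = np.array(active)
        s = np.sign(c[A])
        G = Xs[:, A].T @ Xs[:, A]
        try:
            GA1 = np.linalg.solve(G, s)
        except np.linalg.LinAlgError:
            logger.warning("singular active-set Gram matrix; terminating path early")
            active.pop()
            is_active[A[-1]] = False
            break
        denom = float(s @ GA1)
        if denom <= 0:
            logger.warning("non-positive equiangular norm; terminating path early")
            break
        AA = 1.0 / np.sqrt(denom)
        d_A = AA * GA1                       # coefficient direction on active set
        u = Xs[:, A] @ d_A                   # equiangular vector, ||u|| = 1
        a = Xs.T @ u

        gamma_lsq = C / AA                   # reach zero correlation (full LS)
        gamma = gamma_lsq
        inactive = np.flatnonzero(~is_active)
        if inactive.size:
            with np.errstate(divide="ignore", invalid="ignore"):
                g1 = (C - c[inactive]) / (AA - a[inactive])
                g2 = (C + c[inactive]) / (AA + a[inactive])
            cands = np.concatenate([g1, g2])
            cands = cands[(cands > 1e-14 * max(gamma_lsq, 1.0)) & np.isfinite(cands)]
            if cands.size:
                gamma = min(gamma, float(cands.min()))

        drop_idx = -1
        with np.errstate(divide="ignore", invalid="ignore"):
            g_drop = -beta[A] / d_A
        pos = (g_drop > 1e-14 * max(gamma_lsq, 1.0)) & np.isfinite(g_drop)
        if pos.any():
            g_min = float(g_drop[pos].min())
            if g_min < gamma:
                gamma = g_min
                drop_idx = int(A[pos][np.argmin(g_drop[pos])])

        beta[A] += gamma * d_A
        if drop_idx >= 0:
            beta[drop_idx] = 0.0
            active.remove(drop_idx)
            is_active[drop_idx] = False
            drop_pending = True

        r = ys - Xs @ beta
        c = Xs.T @ r
        C = float(np.abs(c).max())
        new_lam = C / n
        if new_lam >= lambdas[-1] - 1e-15:
            new_lam = min(new_lam, lambdas[-1] * (1 - 1e-12))
        lambdas.append(new_lam)
        coefs.append(beta.copy())
        active_sets.append(np.array(sorted(active), dtype=int))
        if new_lam <= 0:
            break

    return LarsPath(
        lambdas=np.array(lambdas),
        coefs=np.array(coefs),
        active_sets=active_sets,
        n_samples=n,
    )


def solution_at_lambda(path: LarsPath, lam: float) -> np.ndarray:
    """Coefficients at penalty ``lam`` by linear interpolation between knots.

    Exact for the lasso path (solutions are piecewise linear in lambda).
    Above ``lambda_max`` -> zeros; at or below the final knot -> final knot.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    lams = path.lambdas
    if lam >= lams[0]:
        return np.zeros(path.coefs.shape[1])
    if lam <= lams[-1]:
        return path.coefs[-1].copy()
    k = int(np.searchsorted(-lams, -lam, side="right"))  # lams[k-1] > lam >= lams[k]
    lo, hi = lams[k], lams[k - 1]
    t = (lam - lo) / (hi - lo)
    return (1 - t) * path.coefs[k] + t * path.coefs[k - 1]


def lars_l2_augment(Xs: np.ndarray, ys: np.ndarray, lam: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-style augmentation ``[Xs; sqrt(n*lam) I], [ys; 0]``.

    Least squares on the augmented pair equals ridge with penalty ``lam``
    in the same 1/(2n) objective scaling used by the L1 path.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n, p = Xs.shape
    X_aug = np.vstack([Xs, np.sqrt(lam * n) * np.eye(p)])
    y_aug = np.concatenate([ys, np.zeros(p)])
    return X_aug, y_aug


def _knot_rmsecv(X_cols: np.ndarray, y: np.ndarray, k_folds: int, seed: int,
                 max_lv: int) -> float:
    """5-fold RMSECV of a PLSR refit on a candidate variable subset."""
    cap = min(max_lv, X_cols.shape[1], X_cols.shape[0] - 2)
    if cap < 1:
        return np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, curve = plsr.select_lvs_cv(X_cols, y, max_lv=cap, k_folds=k_folds, seed=seed)
    return float(curve.min())


def select_wavelengths(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty: str = "L1",
    cv_seed: int = 0,
    wavelengths: np.ndarray | None = None,
    max_steps: int | None = None,
    max_active: int | None = None,
    cv_max_lv: int = 12,
) -> SelectionResult:
    """Active wavelength set at regularization ``lam``.

    L1: nonzero coefficients of the lasso path solution at ``lam``.
    L2: the lasso path is run on the ``lam``-augmented design and the knot
    whose active set minimizes 5-fold PLSR RMSECV is chosen (ridge alone
    never zeroes coefficients, so sparsity comes from path stopping).
    """
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float)
    Xs, ys, info = standardize_for_path(X, y, wavelengths)

    if penalty == "L1":
        path = lars_path_l1(Xs, ys, max_steps=max_steps, max_active=max_active)
        beta_s = solution_at_lambda(path, lam)
        nz = np.flatnonzero(np.abs(beta_s) > 0)
        if nz.size == 0:
            raise EmptySelectionError(
                f"no active wavelength at lambda={lam:g} "
                f"(lambda_max={path.lambda_max:g}); try a smaller lambda"
            )
    else:
        X_aug, y_aug = lars_l2_augment(Xs, ys, lam)
        path = lars_path_l1(X_aug, y_aug, max_steps=max_steps,
                            max_active=max_active)
        best_k, best_score = -1, np.inf
        for k, A in enumerate(path.active_sets):
            if A.size == 0:
                continue
            score = _knot_rmsecv(X[:, info.kept[A]], y, 5, cv_seed, cv_max_lv)
            if score < best_score - 1e-12:
                best_score, best_k = score, k
        if best_k < 0:
            raise EmptySelectionError(
                f"no non-empty knot on the L2-augmented path at lambda={lam:g}"
            )
        beta_s = path.coefs[best_k]
        nz = np.flatnonzero(np.abs(beta_s) > 0)

    orig = info.kept[nz]
    coef_orig = beta_s[nz] / info.x_sd[orig]
    intercept = info.y_mean - float(info.x_mean[orig] @ coef_orig)
    result = SelectionResult(
        lam=float(lam),
        penalty=penalty,
        indices=orig,
        wavelengths_nm=np.asarray(wavelengths, dtype=float)[orig],
        coefficients=coef_orig,
        intercept=intercept,
    )
    logger.info("%s selection at lambda=%g: %d variable(s)", penalty, lam, result.count)
    return result


def save_selection(result: SelectionResult, path) -> None:
    import json

    payload = {
        "lambda": result.lam,
        "penalty": result.penalty,
        "indices": result.indices.tolist(),
        "wavelengths_nm": result.wavelengths_nm.tolist(),
        "coefficients": result.coefficients.tolist(),
        "intercept": result.intercept,
        "count": result.count,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_selection(path) -> SelectionResult:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return SelectionResult(
        lam=float(d["lambda"]),
        penalty=str(d["penalty"]),
        indices=np.array(d["indices"], dtype=int),
        wavelengths_nm=np.array(d["wavelengths_nm"], dtype=float),
        coefficients=np.array(d["coefficients"], dtype=float),
        intercept=float(d["intercept"]),
    )


def scan_lambda(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    lambdas,
    penalty: str = "L1",
    wavelengths: np.ndarray | None = None,
    cv_seed: int = 0,
    max_lv: int = 15,
    r_mode: str = "paper",
    max_steps: int | None = None,
):
    """Per-lambda selection + reduced PLSR refit, evaluated on held-out data.

    Returns a pandas DataFrame with columns lambda, n_variables, Rp, RMSEP
    (NaN metrics and zero count flag an empty selection at that lambda; a
    warning is emitted when every lambda comes up empty). Duplicate
    lambdas are dropped, order preserved.
    """
    import pandas as pd

    lambdas = list(dict.fromkeys(float(v) for v in lambdas))
    if not lambdas:
        raise ValueError("empty lambda grid")
    rows = []
    n_empty = 0
    for lam in lambdas:
        try:
            sel = select_wavelengths(X_cal, y_cal, lam, penalty=penalty,
                                     cv_seed=cv_seed, wavelengths=wavelengths,
                                     max_steps=max_steps)
        except EmptySelectionError:
            rows.append({"lambda": lam, "n_variables": 0,
                         "Rp": np.nan, "RMSEP": np.nan})
            n_empty += 1
            continue
        cols = sel.indices
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_lv, _ = plsr.select_lvs_cv(X_cal[:, cols], y_cal,
                                         max_lv=min(max_lv, cols.size),
                                         seed=cv_seed)
            model = plsr.fit_plsr(X_cal[:, cols], y_cal, n_lv)
        m = plsr.compute_metrics(y_pred, plsr.predict(model, X_pred[:, cols]),
                                 mode=r_mode)
        rows.append({"lambda": lam, "n_variables": sel.count,
                     "Rp": m.r, "RMSEP": m.rmse})
    if n_empty == len(lambdas):
        warnings.warn("selection empty at every lambda in the grid", stacklevel=2)
    return pd.DataFrame(rows)


def choose_lambda_l1_cv(X: np.ndarray, y: np.ndarray, lambdas=None,
                        k_folds: int = 5, seed: int = 0) -> float:
    """Pick lambda for L1 selection by k-fold lasso-prediction RMSECV.

    One path per training fold serves all candidate lambdas. Ties break
    toward the larger (sparser) lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if lambdas is None:
        Xs0, ys0, _ = standardize_for_path(X, y)
        lam_max = float(np.abs(Xs0.T @ ys0).max()) / n
        lambdas = lam_max * np.logspace(-3, -0.3, 12)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    folds = plsr._cv_folds(n, k_folds, seed)
    sq_err = np.zeros(lambdas.size)
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xs, ys, info = standardize_for_path(X[mask], y[mask])
        path = lars_path_l1(Xs, ys)
        Xt = (X[test_idx][:, info.kept] - info.x_mean[info.kept]) / info.x_sd[info.kept]
        for i, lam in enumerate(lambdas):
            beta = solution_at_lambda(path, lam)
            pred = Xt @ beta + info.y_mean
            sq_err[i] += float(np.sum((pred - y[test_idx]) ** 2))
    best = int(np.argmin(sq_err))  # argmin returns first (largest lambda) on ties
    return float(lambdas[best])
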