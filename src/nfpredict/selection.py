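"""Automatic selection of the group-penalty weight lambda.

The learning session is split K times (default 50) into 90% training /
10% cross-validation index sets.  For each candidate lambda, models are
fitted on every training set and the summed train + cross-validation
normalized MSE is the selection criterion; scanning stops early once the
mean nonzero count over splits drops below 2 (larger lambdas could only
produce null models), and ties favour the larger (sparser) lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optimize import FitConfig, fit_activation_pattern, lipschitz_constant

__all__ = ["SplitScheme", "LambdaGrid", "nmse", "make_splits", "select_lambda",
           "default_lambda_grid"]


def default_lambda_grid(
    lo: float = 100.0, hi: float = 3000.0, n: int = 15
) -> np.ndarray:
    """The default linear candidate grid: 15 values from 100 to 3000."""
    return np.linspace(lo, hi, n)


@dataclass
class SplitScheme:
    """K random partitions of {0..T-1} into training and CV index sets."""

    K: int
    train_frac: float
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for r, cv in self.splits:
            if np.intersect1d(r, cv).size:
                raise ValueError("training and CV sets overlap")


@dataclass
class LambdaGrid:
    """Candidate lambdas with per-lambda selection diagnostics."""

    values: np.ndarray
    nmse_train: np.ndarray | None = None
    nmse_cv: np.ndarray | None = None
    mean_l0: np.ndarray | None = None
    criterion: np.ndarray | None = None
    selected: float | None = None
    stopped_at: int | None = None
    n_fits: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty lambda grid")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("lambda grid must be strictly increasing")


def nmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Normalized mean squared error: sum (y - yhat)^2 / sum (y - ybar)^2."""
    y = np.asarray(getattr(y, "values", y), dtype=float)
    y_hat = np.asarray(getattr(y_hat, "values", y_hat), dtype=float)
    if len(y) != len(y_hat):
        raise ValueError("series lengths differ")
    if len(y) < 2:
        raise ValueError("need at least two samples")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise ValueError("NMSE undefined for a constant reference series")
    return float(np.sum((y - y_hat) ** 2)) / denom


def make_splits(
    T: int, K: int = 50, train_frac: float = 0.9, seed: int = 0
) -> SplitScheme:
    """K independent uniform-random partitions, reproducible by seed."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if T < 10:
        raise ValueError(f"T={T} too small to split")
    n_cv = int(round((1.0 - train_frac) * T))
    if n_cv < 1:
        raise ValueError("cross-validation set would be empty")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(K):
        perm = rng.permutation(T)
        cv = np.sort(perm[:n_cv])
        train = np.sort(perm[n_cv:])
        splits.append((train, cv))
    return SplitScheme(K=K, train_frac=train_frac, seed=seed, splits=splits)


def select_lambda(
    xc,
    y,
    grid,
    scheme: SplitScheme,
    rho: float = 1500.0,
    max_iter: int = 2000,
    rel_tol: float = 1e-8,
    sparsity_stop: float = 2.0,
    tie_rel_tol: float = 1e-9,
) -> LambdaGrid:
    """Scan the grid in ascending order and pick the NMSE-optimal lambda.

    For each lambda the criterion is sum_k [NMSE(train_k) + NMSE(cv_k)].
    Scanning stops after the first lambda whose mean nonzero count over
    splits falls below ``sparsity_stop``; among the evaluated lambdas the
    argmin is selected, with criterion ties (within ``tie_rel_tol``
    relative) resolved toward the larger lambda.  Warm starts carry each
    split's solution along the path.
    """
    if not isinstance(grid, LambdaGrid):
        grid = LambdaGrid(values=np.asarray(grid, dtype=float))
    X = xc.values if hasattr(xc, "values") and not isinstance(xc, np.ndarray) else np.asarray(xc)
    yv = np.asarray(getattr(y, "values", y), dtype=float)
    if X.shape[0] != len(yv):
        raise ValueError("design and score lengths differ")

    lambdas = grid.values
    n_lam = len(lambdas)
    sum_train = np.full(n_lam, np.nan)
    sum_cv = np.full(n_lam, np.nan)
    mean_l0 = np.full(n_lam, np.nan)
    n_fits = 0
    stopped_at = None

    # per-split precomputation: the Lipschitz constant of each training
    # subdesign is reused across the whole lambda path
    lips = [lipschitz_constant(X[r]) for r, _ in scheme.splits]
    warm = [None] * scheme.K

    evaluated = 0
    for i, lam in enumerate(lambdas):
        tr_total = cv_total = l0_total = 0.0
        for k, (r_idx, cv_idx) in enumerate(scheme.splits):
            cfg = FitConfig(lambda_=float(lam), rho=rho,
                            max_iter=max_iter, rel_tol=rel_tol)
            pat = fit_activation_pattern(
                X[r_idx], yv[r_idx], cfg, init=warm[k], lipschitz=lips[k]
            )
            n_fits += 1
            warm[k] = pat.weights
            a = pat.weights.ravel()
            Xr = X[r_idx].reshape(len(r_idx), -1)
            Xcv = X[cv_idx].reshape(len(cv_idx), -1)
            tr_total += nmse(yv[r_idx], Xr @ a)
            cv_total += nmse(yv[cv_idx], Xcv @ a)
            l0_total += pat.nnz
        sum_train[i] = tr_total
        sum_cv[i] = cv_total
        mean_l0[i] = l0_total / scheme.K
        evaluated = i + 1
        if mean_l0[i] < sparsity_stop:
            stopped_at = i
            break

    criterion = sum_train + sum_cv
    evald = criterion[:evaluated]
    if not np.any(np.isfinite(evald)):
        raise RuntimeError("lambda selection failed: no finite criterion values")
    best = float(np.nanmin(evald))
    # ties (within tolerance) go to the largest candidate, favouring sparsity
    tied = np.nonzero(evald <= best + tie_rel_tol * max(1.0, abs(best)))[0]
    selected = float(lambdas[tied[-1]])

    return LambdaGrid(
        values=lambdas,
        nmse_train=sum_train / scheme.K,
        nmse_cv=sum_cv / scheme.K,
        mean_l0=mean_l0,
        criterion=criterion,
        selected=selected,
        stopped_at=stopped_at,
        n_fits=n_fits,
    )
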