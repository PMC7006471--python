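"""l21+1-regularized least squares solved by FISTA.

The activation pattern alpha (M features x B bands) minimizes

    sum_t 1/2 (y(t) - <X(t), alpha>)^2 + lambda ||alpha||_21 + rho ||alpha||_1

where ||alpha||_21 = sum_m sqrt(sum_b alpha_mb^2) selects few
(electrode, delay) rows and the l1 term zeroes irrelevant bands inside a
surviving row.  The proximal map of the combined penalty is closed form:
elementwise soft-threshold by rho, then row-wise group shrinkage by
lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignTensor, FrequencyBandSet

__all__ = [
    "ActivationPattern",
    "FitConfig",
    "linear_score",
    "grad_data_term",
    "lipschitz_constant",
    "prox_l21_1",
    "penalty",
    "objective",
    "fit_activation_pattern",
]


@dataclass
class ActivationPattern:
    """Fitted M x B weight matrix with its regularization metadata."""

    weights: np.ndarray
    lambda_: float = 0.0
    rho: float = 0.0
    feature_labels: list[tuple[str, int]] | None = None
    band_set: FrequencyBandSet | None = None
    objective_trace: np.ndarray | None = None
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be an M x B matrix")

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def sparsity(self) -> float:
        """Proportion of exactly-zero coefficients."""
        return 1.0 - self.nnz / self.weights.size

    def block(self, delay_s: int) -> np.ndarray:
        if self.feature_labels is None:
            raise ValueError("pattern has no feature labels")
        rows = [i for i, (_, d) in enumerate(self.feature_labels) if d == delay_s]
        if not rows:
            raise KeyError(f"no features with delay {delay_s}")
        return self.weights[rows, :]


@dataclass
class FitConfig:
    lambda_: float = 0.0
    rho: float = 1500.0
    max_iter: int = 2000
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.rho < 0:
            raise ValueError("lambda_ and rho must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


def _as_array(x) -> np.ndarray:
    if isinstance(x, DesignTensor):
        return x.values
    return np.asarray(x, dtype=float)


def _as_values(y) -> np.ndarray:
    values = getattr(y, "values", y)
    return np.asarray(values, dtype=float)


def linear_score(x_t: np.ndarray, alpha) -> float:
    """<X(t), alpha> = sum_{m,b} X(t, m, b) alpha(m, b)."""
    a = alpha.weights if isinstance(alpha, ActivationPattern) else np.asarray(alpha)
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != a.shape:
        raise ValueError(f"shape mismatch: x_t {x_t.shape} vs alpha {a.shape}")
    return float(np.sum(x_t * a))


def grad_data_term(xc, y, alpha) -> np.ndarray:
    """Gradient of the data term: sum_t -X(t) (y(t) - <X(t), alpha>)."""
    X = _as_array(xc)
    yv = _as_values(y)
    a = alpha.weights if isinstance(alpha, ActivationPattern) else np.asarray(alpha)
    if X.shape[0] != len(yv):
        raise ValueError(f"design has {X.shape[0]} rows but y has {len(yv)}")
    if X.shape[1:] != a.shape:
        raise ValueError(f"shape mismatch: design {X.shape[1:]} vs alpha {a.shape}")
    resid = yv - np.einsum("tmb,mb->t", X, a)
    return -np.einsum("tmb,t->mb", X, resid)


def lipschitz_constant(xc, tol: float = 1e-8, max_iter: int = 1000) -> float:
    """Largest eigenvalue of X_V^T X_V, X_V the T x (M*B) unfolding.

    Power iteration on the Gram operator; this is the squared spectral
    norm of the unfolded design and the Lipschitz constant of the data
    term's gradient.
    """
    X = _as_array(xc)
    if X.size == 0:
        raise ValueError("empty design")
    T = X.shape[0]
    Xv = X.reshape(T, -1)
    rng = np.random.default_rng(0)  # fixed: the result is deterministic anyway
    v = rng.standard_normal(Xv.shape[1])
    nv = np.linalg.norm(v)
    if nv == 0:
        return 0.0
    v /= nv
    lam = 0.0
    for _ in range(max_iter):
        w = Xv.T @ (Xv @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        lam_new = float(v @ w)
        v = w / nw
        if abs(lam_new - lam) <= tol * max(1.0, abs(lam_new)):
            return lam_new
        lam = lam_new
    return lam


def prox_l21_1(Y: np.ndarray, lambda_: float, rho: float) -> np.ndarray:
    """Proximal map of lambda ||.||_21 + rho ||.||_1 (closed form).

    Soft-threshold every entry by rho, then shrink each row by the group
    factor (1 - lambda / ||row||_2)^+; rows whose soft-thresholded norm is
    at most lambda vanish entirely.  Setting rho = 0 recovers the group
    (l21) prox, lambda = 0 the elementwise (l1) prox.
    """
    if lambda_ < 0 or rho < 0:
        raise ValueError("lambda_ and rho must be non-negative")
    Y = np.asarray(Y, dtype=float)
    soft = np.sign(Y) * np.maximum(np.abs(Y) - rho, 0.0)
    if lambda_ == 0:
        return soft  # pure l1 case; also avoids row-norm underflow
    row_norm = np.sqrt(np.sum(soft**2, axis=-1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(row_norm > 0, np.maximum(1.0 - lambda_ / row_norm, 0.0), 0.0)
    return soft * factor


def penalty(alpha: np.ndarray, lambda_: float, rho: float) -> float:
    """phi_lambda(alpha) = lambda ||alpha||_21 + rho ||alpha||_1."""
    a = np.asarray(alpha, dtype=float)
    return float(
        lambda_ * np.sum(np.sqrt(np.sum(a**2, axis=-1))) + rho * np.sum(np.abs(a))
    )


def objective(xc, y, alpha, lambda_: float, rho: float) -> float:
    """Penalized half sum-of-squares objective at ``alpha``."""
    X = _as_array(xc)
    yv = _as_values(y)
    a = alpha.weights if isinstance(alpha, ActivationPattern) else np.asarray(alpha)
    resid = yv - X.reshape(len(yv), -1) @ a.ravel()
    return 0.5 * float(resid @ resid) + penalty(a, lambda_, rho)


def fit_activation_pattern(
    xc,
    y,
    cfg: FitConfig,
    init: np.ndarray | None = None,
    lipschitz: float | None = None,
) -> ActivationPattern:
    """FISTA: gradient step of 1/L on the data term, then the prox.

    Standard momentum schedule t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2 with
    extrapolation point z_k.  Stops after ``cfg.max_iter`` iterations or
    when the relative objective change falls below ``cfg.rel_tol``.
    ``init`` (default zero) and a precomputed ``lipschitz`` constant allow
    warm starts along a regularization path.
    """
    X = _as_array(xc)
    yv = _as_values(y)
    if X.shape[0] != len(yv):
        raise ValueError(f"design has {X.shape[0]} rows but y has {len(yv)}")
    T = X.shape[0]
    M, B = X.shape[1], X.shape[2]
    Xv = X.reshape(T, M * B)
    L = lipschitz_constant(X) if lipschitz is None else float(lipschitz)
    if L <= 0:
        raise ValueError("degenerate (all-zero) design: Lipschitz constant is 0")

    lam, rho = cfg.lambda_, cfg.rho
    alpha = np.zeros((M, B)) if init is None else np.array(init, dtype=float)
    z = alpha.copy()
    t_k = 1.0
    trace = []

    def obj(a: np.ndarray) -> float:
        r = yv - Xv @ a.ravel()
        return 0.5 * float(r @ r) + penalty(a, lam, rho)

    prev_obj = obj(alpha)
    trace.append(prev_obj)
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        grad = (Xv.T @ (Xv @ z.ravel() - yv)).reshape(M, B)
        alpha_new = prox_l21_1(z - grad / L, lam / L, rho / L)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
        z = alpha_new + ((t_k - 1.0) / t_next) * (alpha_new - alpha)
        alpha, t_k = alpha_new, t_next
        cur_obj = obj(alpha)
        trace.append(cur_obj)
        if abs(prev_obj - cur_obj) <= cfg.rel_tol * max(1.0, abs(prev_obj)):
            break
        prev_obj = cur_obj

    labels = xc.feature_labels if isinstance(xc, DesignTensor) else None
    bands = xc.band_set if isinstance(xc, DesignTensor) else None
    return ActivationPattern(
        weights=alpha,
        lambda_=lam,
        rho=rho,
        feature_labels=labels,
        band_set=bands,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
    )
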