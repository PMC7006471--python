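"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own closed-form proximal map and
FISTA loop: the prox oracle is Douglas-Rachford splitting built from the
elementary soft-threshold and block-shrinkage proxes, and the full-problem
oracle is Davis-Yin three-operator splitting.  Both converge to the exact
minimizers of the convex objectives they target.
"""

from __future__ import annotations

import numpy as np


def _soft(z: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)


def _block_shrink(z: np.ndarray, thr: float) -> np.ndarray:
    nrm = np.sqrt((z**2).sum(axis=-1, keepdims=True))
    safe = np.where(nrm > 0, nrm, 1.0)
    return z * np.where(nrm > 0, np.maximum(1.0 - thr / safe, 0.0), 0.0)


def prox_oracle(Y: np.ndarray, lam: float, rho: float,
                n_iter: int = 3000, t: float = 1.0) -> np.ndarray:
    """Minimize lam*||a||_21 + rho*||a||_1 + 1/2||Y - a||^2 by Douglas-Rachford."""
    Y = np.asarray(Y, dtype=float)

    def prox_tF(z):  # 1/2||Y-a||^2 + rho||a||_1
        return _soft((z + t * Y) / (1.0 + t), t * rho / (1.0 + t))

    z = np.zeros_like(Y)
    for _ in range(n_iter):
        a = prox_tF(z)
        w = _block_shrink(2 * a - z, t * lam)
        z = z + w - a
    return prox_tF(z)


def solver_oracle(X: np.ndarray, y: np.ndarray, lam: float, rho: float,
                  n_iter: int = 20000) -> np.ndarray:
    """Minimize the penalized least-squares objective by Davis-Yin splitting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    T, M, B = X.shape
    Xv = X.reshape(T, -1)
    step = 1.0 / np.linalg.norm(Xv, 2) ** 2
    z = np.zeros(M * B)
    for _ in range(n_iter):
        a_g = _soft(z, step * rho)
        grad = Xv.T @ (Xv @ a_g - y)
        a_f = _block_shrink(
            (2 * a_g - z - step * grad).reshape(M, B), step * lam
        ).ravel()
        z = z + a_f - a_g
    return _soft(z, step * rho).reshape(M, B)


def band_power_oracle(seg: np.ndarray, srate: float,
                      band: tuple[float, float]) -> float:
    """Hand-rolled Hamming periodogram band power for one window."""
    from scipy.signal import get_window

    n = len(seg)
    w = get_window("hamming", n)
    spec = np.fft.rfft(w * seg)
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    # one-sided PSD with Hamming power normalization
    psd = (np.abs(spec) ** 2) / (srate * np.sum(w**2))
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    mask = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    return float(psd[mask].mean())
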