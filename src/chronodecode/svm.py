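"""Batched linear soft-margin SVM.

Time-resolved pairwise decoding solves an enormous number of tiny,
identically shaped SVM problems (one per condition pair x timepoint x fold x
repetition, typically with 4-6 training samples each). Fitting them one at a
time through a generic library carries milliseconds of per-call overhead;
this module instead solves the dual of every problem in a batch
simultaneously with vectorized SMO-style pair updates, which is exact for
the same objective (hinge loss, L2 margin, cost C) and orders of magnitude
faster. Predictions agree with libsvm on the same problems (see tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_linear_svm_batch", "decision_function", "predict"]


def fit_linear_svm_batch(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-8,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a linear soft-margin SVM to every problem in a batch.

    Parameters
    ----------
    X : (B, n, d)
        B problems, each with the same n training samples count and d features.
    y : (n,)
        Labels in {-1, +1}, shared across the batch.
    C : float
        Box constraint (cost parameter).

    Returns
    -------
    w : (B, d), b : (B,)
        Primal weight vectors and intercepts; decision = X @ w + b.

    Notes
    -----
    Solves  min_a 0.5 a'Qa - 1'a  s.t.  0 <= a <= C,  sum a_i y_i = 0
    with Q_ij = y_i y_j <x_i, x_j>, by sweeping analytic two-variable
    updates over all index pairs until the KKT gap of every problem falls
    below ``tol``. The intercept is the mean KKT residual over free support
    vectors, falling back to the margin midpoint when no free SV exists.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (batch, samples, features)")
    B, n, d = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one label per training sample")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")

    K = np.einsum("bnd,bmd->bnm", X, X)
    Y = y[:, None] * y[None, :]
    Q = K * Y
    alpha = np.zeros((B, n))
    grad = -np.ones((B, n))  # d/da (0.5 a'Qa - 1'a) = Qa - 1

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    quad = {
        (i, j): np.maximum(Q[:, i, i] + Q[:, j, j] - 2.0 * Q[:, i, j] * Y[i, j], 1e-12)
        for (i, j) in pairs
    }

    for sweep in range(max_sweeps):
        for i, j in pairs:
            s = Y[i, j]
            g = grad[:, i] - s * grad[:, j]
            t = -g / quad[(i, j)]
            if s > 0:
                lo = np.maximum(-alpha[:, i], alpha[:, j] - C)
                hi = np.minimum(C - alpha[:, i], alpha[:, j])
            else:
                lo = np.maximum(-alpha[:, i], -alpha[:, j])
                hi = np.minimum(C - alpha[:, i], C - alpha[:, j])
            t = np.clip(t, lo, hi)
            alpha[:, i] += t
            alpha[:, j] -= s * t
            grad += t[:, None] * (Q[:, i, :] - s * Q[:, j, :])
        if sweep % 4 == 3 or sweep == max_sweeps - 1:
            if _max_kkt_gap(alpha, grad, y, C) < tol:
                break

    ay = alpha * y[None, :]
    fx = np.einsum("bn,bnm->bm", ay, K)  # f(x_i) without intercept
    resid = y[None, :] - fx
    free = (alpha > 1e-9 * C) & (alpha < C * (1 - 1e-9))
    n_free = free.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        b_free = np.where(n_free > 0, (resid * free).sum(axis=1) / np.maximum(n_free, 1), 0.0)
    pos_min = np.where(y[None, :] > 0, fx, np.inf).min(axis=1)
    neg_max = np.where(y[None, :] < 0, fx, -np.inf).max(axis=1)
    b_mid = -(pos_min + neg_max) / 2.0
    b = np.where(n_free > 0, b_free, b_mid)
    w = np.einsum("bn,bnd->bd", ay, X)
    return w, b


def _max_kkt_gap(alpha: np.ndarray, grad: np.ndarray, y: np.ndarray, C: float) -> float:
    # optimality: max_{i in I_up} (-y_i grad_i) <= min_{i in I_low} (-y_i grad_i)
    v = -y[None, :] * grad
    up = ((y[None, :] > 0) & (alpha < C - 1e-12)) | ((y[None, :] < 0) & (alpha > 1e-12))
    low = ((y[None, :] > 0) & (alpha > 1e-12)) | ((y[None, :] < 0) & (alpha < C - 1e-12))
    m_up = np.where(up, v, -np.inf).max(axis=1)
    m_low = np.where(low, v, np.inf).min(axis=1)
    gap = m_up - m_low
    gap = gap[np.isfinite(gap)]
    return float(gap.max()) if gap.size else 0.0


def decision_function(w: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Scores for test batch X (B, m, d) -> (B, m)."""
    return np.einsum("bd,bmd->bm", w, X) + b[:, None]


def predict(w: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted -1/+1 labels; exact zeros break toward +1."""
    return np.where(decision_function(w, b, X) >= 0, 1.0, -1.0)
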