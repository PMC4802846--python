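"""Proximal-gradient solver for the l1-penalized least-squares blocks.

Each block update of the alternating minimization has the form

    min_W  ||D - G W Q||_F^2 + lam * ||W||_1
           (optionally: W[i, j] = 0 wherever mask[i, j] = 0)

with ``G`` and ``Q`` fixed.  The smooth part has exact Lipschitz constant
``2 * sigma_max(G)^2 * sigma_max(Q)^2``, so FISTA with a fixed step needs
no line search.  Because accelerated proximal gradient is not monotone,
the solver tracks the best iterate seen (the starting point included) and
returns it — block updates therefore never increase the objective.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["solve_l1_ls"]


def _spectral_sq(M: Optional[np.ndarray]) -> float:
    """Largest squared singular value; 1.0 for an identity placeholder."""
    if M is None:
        return 1.0
    # eigvalsh on the smaller Gram matrix is cheaper than a full SVD
    if M.shape[0] <= M.shape[1]:
        gram = M @ M.T
    else:
        gram = M.T @ M
    return float(np.linalg.eigvalsh(gram)[-1])


def solve_l1_ls(
    D: np.ndarray,
    Q: Optional[np.ndarray],
    lam: float,
    W0: np.ndarray,
    G: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> np.ndarray:
    """Minimize ``||D - G W Q||_F^2 + lam ||W||_1`` over ``W`` by FISTA.

    Parameters
    ----------
    D : target matrix.
    Q : right factor (``None`` means identity).
    lam : nonnegative l1 weight.
    W0 : starting point (warm start from the previous sweep).
    G : left factor (``None`` means identity).
    mask : optional binary matrix; entries where ``mask == 0`` are frozen
        at zero (support-restricted variants).
    max_iter, tol : iteration cap and relative objective-change tolerance.

    Returns
    -------
    The best (lowest-objective) iterate encountered.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")

    def apply_mask(W: np.ndarray) -> np.ndarray:
        if mask is not None:
            W = W * mask
        return W

    def residual(W: np.ndarray) -> np.ndarray:
        GW = W if G is None else G @ W
        return D - (GW if Q is None else GW @ Q)

    def objective(W: np.ndarray) -> float:
        R = residual(W)
        return float(np.sum(R * R)) + lam * float(np.abs(W).sum())

    lip = 2.0 * _spectral_sq(G) * _spectral_sq(Q)
    if lip == 0:  # G or Q identically zero: any feasible W gives the same loss
        return apply_mask(np.zeros_like(W0))
    step = 1.0 / lip
    thresh = lam * step

    W = apply_mask(np.asarray(W0, float).copy())
    best_W, best_obj = W.copy(), objective(W)
    Y = W.copy()
    t = 1.0
    prev_obj = best_obj
    for _ in range(max_iter):
        R = residual(Y)
        if not np.all(np.isfinite(R)):
            raise FloatingPointError("non-finite gradient in l1 solver")
        grad = -2.0 * (R if G is None else G.T @ R)
        if Q is not None:
            grad = grad @ Q.T
        W_new = Y - step * grad
        # soft-threshold, then re-impose the support mask
        W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - thresh, 0.0)
        W_new = apply_mask(W_new)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Y = W_new + ((t - 1.0) / t_new) * (W_new - W)
        W, t = W_new, t_new
        obj = objective(W)
        if obj < best_obj:
            best_obj, best_W = obj, W.copy()
        denom = max(abs(prev_obj), 1e-12)
        if abs(prev_obj - obj) <= tol * denom:
            break
        prev_obj = obj
    return best_W
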