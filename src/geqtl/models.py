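"""Model fitting: Lasso and LORS baselines and the geQTL variants.

The geQTL model decomposes the gene-SNP association matrix into a
rank-``M`` group-wise part ``B @ A`` (M latent factors, each linking a
set of SNPs to a set of genes) and a sparse individual part ``C``, while
a nuclear-norm-penalized matrix ``L`` absorbs hidden-confounder
variation:

    min_{A,B,C,L}  ||Z - L - (B A + C) X||_F^2
                   + rho ||L||_* + alpha ||A||_1 + beta ||B||_1 + pen(C)

with ``pen(C) = gamma ||C||_1`` (variants ``geqtl`` and ``geqtl_plus``)
or ``gamma ||C||_2^2`` (``geqtl_ridge``).  The two accelerated variants
restrict the support of ``C`` to a correlation-screening mask ``R``:
only gene-SNP pairs whose marginal correlation is significant at a given
p-value may receive an individual association.

Fitting is block-coordinate descent.  The ``L`` update is exact
(singular-value soft-thresholding of the residual); ``A``, ``B`` and the
l1 ``C`` update use a proximal-gradient solver; the ridge ``C`` update is
a row-wise closed form.  Every block update is guaranteed not to increase
the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import BaselineModel, GeQTLModel, nuclear_norm, svt
from .solvers import solve_l1_ls

__all__ = [
    "FitOptions",
    "ScreeningMask",
    "fit_lasso",
    "fit_lors",
    "screen",
    "build_projector",
    "update_L",
    "update_A",
    "update_B",
    "update_C_l1",
    "update_C_ridge",
    "fit_geqtl",
    "cross_validate",
]

#: Relative tolerance for the "objective never increases" guarantee.
_MONOTONE_RTOL = 1e-9


@dataclass
class FitOptions:
    """Knobs of the alternating minimization (not model hyperparameters)."""

    max_sweeps: int = 100
    tol: float = 1e-6
    inner_max_iter: int = 300
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class ScreeningMask:
    """Binary ``N x K`` indicator of which ``C`` entries may be nonzero."""

    R: np.ndarray
    threshold_r: float
    pvalue: float

    @property
    def density(self) -> float:
        return float(self.R.mean())


def _ridge_pinv_right(X: np.ndarray, eps_scale: float = 1e-8) -> np.ndarray:
    """Return ``X.T @ (X X^T + eps I)^{-1}`` with a trace-scaled ridge.

    The ridge keeps the inverse defined when ``X X^T`` is singular
    (e.g. more SNPs than samples).
    """
    K = X.shape[0]
    G = X @ X.T
    eps = eps_scale * np.trace(G) / max(K, 1)
    return np.linalg.solve(G + eps * np.eye(K), X).T


def fit_lasso(
    X: np.ndarray,
    Z: np.ndarray,
    eta: float,
    max_iter: int = 2000,
) -> BaselineModel:
    """Multi-gene Lasso: ``min_W ||Z - W X||_F^2 + eta ||W||_1``.

    Each gene's row of ``W`` is an independent lasso regression on the
    SNPs; the coordinate-descent solver from scikit-learn does the work
    (its per-target objective ``(1/2H)||z - X^T w||^2 + a||w||_1``
    matches ours with ``a = eta / (2 H)``).  ``eta = 0`` falls back to
    least squares.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    H = X.shape[1]
    if Z.shape[1] != H:
        raise ValueError("X and Z sample counts differ")
    if eta == 0:
        W = Z @ _ridge_pinv_right(X)
    else:
        from sklearn.linear_model import Lasso

        model = Lasso(alpha=eta / (2.0 * H), fit_intercept=False, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence warnings
            model.fit(X.T, Z.T)
        W = np.atleast_2d(model.coef_)
    return BaselineModel(W=W, L=None, hyperparams={"eta": eta})


def fit_lors(
    X: np.ndarray,
    Z: np.ndarray,
    eta: float,
    rho: float,
    options: Optional[FitOptions] = None,
) -> BaselineModel:
    """LORS: sparse associations plus a nuclear-norm low-rank confounder.

    Alternates an exact ``W`` lasso step (on ``Z - L``) with the exact
    ``L`` update ``L <- svt(Z - W X, rho / 2)``; the objective is
    non-increasing per sweep.
    """
    if eta < 0 or rho < 0:
        raise ValueError("eta and rho must be nonnegative")
    options = options or FitOptions()
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    W = np.zeros((Z.shape[0], X.shape[0]))
    L = np.zeros_like(Z)

    def obj(W, L):
        R = Z - W @ X - L
        return float(np.sum(R * R)) + eta * np.abs(W).sum() + rho * nuclear_norm(L)

    trace = [obj(W, L)]
    converged = False
    for _ in range(options.max_sweeps):
        W = fit_lasso(X, Z - L, eta).W
        L = svt(Z - W @ X, rho / 2.0)
        trace.append(obj(W, L))
        if abs(trace[-2] - trace[-1]) <= options.tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn("LORS did not converge within max_sweeps", RuntimeWarning)
    return BaselineModel(
        W=W,
        L=L,
        hyperparams={"eta": eta, "rho": rho},
        objective_trace=trace,
        converged=converged,
    )


def screen(X: np.ndarray, Z: np.ndarray, pvalue: float = 0.01) -> ScreeningMask:
    """Correlation screening: which gene-SNP pairs may carry a ``C`` entry.

    With rows of ``X`` and ``Z`` standardized to zero mean and unit sum
    of squares, ``r = |Z @ X.T|`` is exactly the matrix of gene-SNP
    Pearson correlations.  The p-value is converted to a correlation
    threshold through the t distribution with ``H - 2`` degrees of
    freedom using ``t = r sqrt(H - 2) / sqrt(1 - r^2)``, and a pair is
    screened in iff its correlation exceeds the threshold.
    """
    if not (0.0 < pvalue <= 1.0):
        raise ValueError("pvalue must lie in (0, 1]")
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    H = X.shape[1]
    if H <= 3:
        raise ValueError("screening needs H > 3 for the t threshold")
    r = np.abs(Z @ X.T)
    np.clip(r, 0.0, 1.0, out=r)
    if pvalue == 1.0:
        thr = 0.0
    else:
        tcrit = stats.t.ppf(1.0 - pvalue / 2.0, df=H - 2)
        thr = float(tcrit / np.sqrt(H - 2 + tcrit**2))
    R = (r > thr).astype(float)
    return ScreeningMask(R=R, threshold_r=thr, pvalue=pvalue)


def build_projector(mask_row: np.ndarray) -> np.ndarray:
    """Column selector ``P`` (``K x l``) for one screening-mask row.

    Column ``t`` of ``P`` has a single 1 at the position of the t-th set
    bit of the mask row, so ``P.T @ P = I_l`` and ``P @ P.T`` is the
    diagonal mask.  Used to express the support-restricted ridge update
    in the reduced space of screened-in SNPs.
    """
    mask_row = np.asarray(mask_row)
    idx = np.flatnonzero(mask_row)
    P = np.zeros((mask_row.size, idx.size))
    P[idx, np.arange(idx.size)] = 1.0
    return P


def update_L(
    Z: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Exact block minimizer over ``L``: ``svt(Z - (B A + C) X, rho / 2)``.

    The factor 1/2 reconciles the ``(1/2)||.||^2`` convention of the
    proximal operator with the unscaled squared loss of the objective.
    """
    return svt(Z - (B @ A + C) @ X, rho / 2.0)


def update_A(
    Z: np.ndarray,
    L: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
    A0: np.ndarray,
    alpha: float,
    max_iter: int = 300,
) -> np.ndarray:
    """l1 subproblem in ``A``: ``min ||(Z - L - C X) - B A X||_F^2 + alpha||A||_1``."""
    if A0.shape[0] == 0:
        return A0.copy()
    D = Z - L - C @ X
    return solve_l1_ls(D, X, alpha, A0, G=B, max_iter=max_iter)


def update_B(
    Z: np.ndarray,
    L: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
    B0: np.ndarray,
    beta: float,
    max_iter: int = 300,
) -> np.ndarray:
    """l1 subproblem in ``B``: ``min ||(Z - L - C X) - B (A X)||_F^2 + beta||B||_1``."""
    if B0.shape[1] == 0:
        return B0.copy()
    D = Z - L - C @ X
    return solve_l1_ls(D, A @ X, beta, B0, max_iter=max_iter)


def update_C_l1(
    Z: np.ndarray,
    L: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    X: np.ndarray,
    C0: np.ndarray,
    gamma: float,
    mask: Optional[np.ndarray] = None,
    max_iter: int = 300,
) -> np.ndarray:
    """l1 subproblem in ``C``; entries outside ``mask`` stay frozen at 0."""
    D = Z - L - B @ A @ X
    return solve_l1_ls(D, X, gamma, C0, mask=mask, max_iter=max_iter)


def update_C_ridge(
    Z: np.ndarray,
    L: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    X: np.ndarray,
    R: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Closed-form support-restricted ridge update of ``C``.

    Row ``i`` solves ``min ||d_i - c_i X||^2 + gamma ||c_i||^2`` subject
    to ``c_i`` being zero outside the screened-in SNPs of mask row ``i``.
    Working in the reduced space of the ``l_i`` selected SNPs,

        c_i[sel] = d_i X_sel^T (X_sel X_sel^T + gamma I_{l_i})^{-1}

    with ``d_i`` the i-th row of ``D = Z - L - B A X``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive for the ridge update")
    D = Z - L - B @ A @ X
    N, K = D.shape[0], X.shape[0]
    C = np.zeros((N, K))
    Rb = np.asarray(R, bool)
    # group genes by identical mask rows so the factorization is shared
    _, inverse = np.unique(Rb, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        sel = Rb[rows[0]]
        l = int(sel.sum())
        if l == 0:
            continue
        Xs = X[sel]
        Gm = Xs @ Xs.T + gamma * np.eye(l)
        # (l x n_rows) solution block, one gene per column
        sol = np.linalg.solve(Gm, Xs @ D[rows].T)
        C[np.ix_(rows, np.flatnonzero(sel))] = sol.T
    return C


def _objective_terms(
    Z, X, A, B, C, L, alpha, beta, gamma, rho, variant: str
) -> float:
    Rm = Z - L - (B @ A + C) @ X
    val = float(np.sum(Rm * Rm)) + rho * nuclear_norm(L)
    val += alpha * float(np.abs(A).sum()) + beta * float(np.abs(B).sum())
    if variant == "geqtl_ridge":
        val += gamma * float(np.sum(C * C))
    else:
        val += gamma * float(np.abs(C).sum())
    return val


def _init_factors(
    W0: np.ndarray, M: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic A, B start: top-M SVD of the initial association
    estimate ``W0`` (the light-lasso fit), split symmetrically.

    Seeding the factors from the lasso estimate (rather than from the
    residual after removing ``C``) starts them on genuine SNP-driven
    structure; confounder variation is left for ``L`` to claim.
    """
    N, K = W0.shape
    if M == 0:
        return np.zeros((0, K)), np.zeros((N, 0))
    U, s, Vt = np.linalg.svd(W0, full_matrices=False)
    M_eff = min(M, s.size)
    root = np.sqrt(s[:M_eff])
    B = U[:, :M_eff] * root
    A = root[:, None] * Vt[:M_eff]
    if M_eff < M:  # pad with zero factors if the estimate is rank-deficient
        A = np.vstack([A, np.zeros((M - M_eff, K))])
        B = np.hstack([B, np.zeros((N, M - M_eff))])
    # fix signs so each A row's largest-magnitude entry is positive
    for m in range(A.shape[0]):
        j = np.argmax(np.abs(A[m]))
        if A[m, j] < 0:
            A[m] *= -1.0
            B[:, m] *= -1.0
    return A, B


#: Fraction of the all-zero lasso penalty used for the C initialization.
_INIT_ETA_FRACTION = 0.1


def init_C_lasso(
    X: np.ndarray, Z: np.ndarray, eta: Optional[float] = None
) -> np.ndarray:
    """Light lasso fit used to initialize ``C`` (and to seed M inference).

    Default penalty is a fixed fraction of ``eta_max = 2 max|Z X^T|``,
    the smallest penalty that zeroes the lasso solution — the glmnet-style
    way to set a scale-free default.
    """
    if eta is None:
        eta_max = 2.0 * float(np.abs(Z @ X.T).max())
        eta = _INIT_ETA_FRACTION * eta_max
    return fit_lasso(X, Z, eta).W


def fit_geqtl(
    X: np.ndarray,
    Z: np.ndarray,
    M: int,
    alpha: float,
    beta: float,
    gamma: float,
    rho: float,
    variant: str = "geqtl",
    options: Optional[FitOptions] = None,
    mask: Optional[ScreeningMask] = None,
) -> GeQTLModel:
    """Fit a geQTL model by block-coordinate descent.

    Per sweep the blocks are visited in the order C, L, A, B.  ``C`` is
    updated by proximal gradient under the l1 penalty (``geqtl``,
    ``geqtl_plus``) or by the exact support-restricted ridge closed form
    (``geqtl_ridge``); ``L`` by singular-value soft-thresholding of the
    residual (exact); ``A`` and ``B`` by proximal gradient.  The sweep
    stops when the relative objective change drops below ``options.tol``.

    ``mask`` is required for ``geqtl_plus`` and ``geqtl_ridge`` and
    confines the support of ``C``.

    Raises
    ------
    RuntimeError
        If any block update increases the objective beyond numerical
        tolerance (it cannot, unless a solver is broken).
    """
    options = options or FitOptions()
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    N, H = Z.shape
    K = X.shape[0]
    if X.shape[1] != H:
        raise ValueError("X and Z sample counts differ")
    if variant not in ("geqtl", "geqtl_plus", "geqtl_ridge"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ("geqtl_plus", "geqtl_ridge") and mask is None:
        raise ValueError(f"variant {variant!r} requires a screening mask")
    if M < 0 or M > min(K, N):
        raise ValueError("M must satisfy 0 <= M <= min(K, N)")
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma), ("rho", rho)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")

    R = mask.R if mask is not None else None

    # ---- initialization: light-lasso C, L = 0, SVD factors for A, B ----
    W0 = init_C_lasso(X, Z)
    C = W0 * R if R is not None else W0.copy()
    L = np.zeros((N, H))
    A, B = _init_factors(W0, M)

    def obj(A, B, C, L):
        return _objective_terms(Z, X, A, B, C, L, alpha, beta, gamma, rho, variant)

    trace = [obj(A, B, C, L)]
    block_trace = [("init", trace[0])]
    converged = False
    n_sweeps = 0
    for sweep in range(options.max_sweeps):
        n_sweeps = sweep + 1
        for block in ("C", "L", "A", "B"):
            if block == "C":
                if variant == "geqtl_ridge":
                    C = update_C_ridge(Z, L, A, B, X, R, gamma)
                else:
                    C = update_C_l1(
                        Z, L, A, B, X, C, gamma, mask=R,
                        max_iter=options.inner_max_iter,
                    )
            elif block == "L":
                L = update_L(Z, A, B, C, X, rho)
            elif block == "A":
                A = update_A(Z, L, B, C, X, A, alpha, max_iter=options.inner_max_iter)
            else:
                B = update_B(Z, L, A, C, X, B, beta, max_iter=options.inner_max_iter)
            val = obj(A, B, C, L)
            prev = block_trace[-1][1]
            if val > prev * (1 + _MONOTONE_RTOL) + 1e-12:
                raise RuntimeError(
                    f"objective increased after {block} update "
                    f"({prev:.6g} -> {val:.6g})"
                )
            block_trace.append((block, val))
        trace.append(block_trace[-1][1])
        if abs(trace[-2] - trace[-1]) <= options.tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn("geQTL did not converge within max_sweeps", RuntimeWarning)

    return GeQTLModel(
        A=A, B=B, C=C, L=L,
        hyperparams={"alpha": alpha, "beta": beta, "gamma": gamma, "rho": rho},
        M=M,
        variant=variant,
        objective_trace=trace,
        block_trace=block_trace,
        converged=converged,
        n_sweeps=n_sweeps,
    )


def cross_validate(
    X: np.ndarray,
    Z: np.ndarray,
    M: int,
    grid: Sequence[dict],
    variant: str = "geqtl",
    n_folds: int = 3,
    options: Optional[FitOptions] = None,
    mask: Optional[ScreeningMask] = None,
    seed: int = 0,
) -> tuple[dict, list]:
    """Pick hyperparameters by k-fold cross-validation over samples.

    Each grid point is a dict with keys ``alpha``, ``beta``, ``gamma``,
    ``rho``.  Folds split the ``H`` samples; the model is fit on the
    training samples and scored by ``||Z_test - (B A + C) X_test||_F^2``
    (the confounder term ``L`` is sample-specific and does not transfer
    to held-out samples, so prediction uses the association matrix only).
    Returns the best parameter dict and the per-point mean scores.
    """
    rng = np.random.default_rng(seed)
    H = X.shape[1]
    if n_folds < 2 or n_folds > H:
        raise ValueError("n_folds must lie in [2, H]")
    perm = rng.permutation(H)
    folds = np.array_split(perm, n_folds)
    results = []
    for params in grid:
        scores = []
        for f in folds:
            train = np.setdiff1d(perm, f)
            model = fit_geqtl(
                X[:, train], Z[:, train], M,
                params["alpha"], params["beta"], params["gamma"], params["rho"],
                variant=variant, options=options, mask=mask,
            )
            Rm = Z[:, f] - model.weights @ X[:, f]
            scores.append(float(np.sum(Rm * Rm)))
        results.append((params, float(np.mean(scores))))
    best = min(results, key=lambda t: t[1])[0]
    return best, results
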