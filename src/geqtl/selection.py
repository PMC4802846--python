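"""Model selection: rank-based inference of M and permutation FDR.

The number of group-wise associations ``M`` equals the rank of the
group-wise product ``B A``.  Given current estimates of the individual
associations ``C`` and the confounder matrix ``L``, the least-squares
estimate of ``B A`` is

    BA_hat = (Z - L - C X) X^T (X X^T)^{-1}

and ``M`` is read off the singular-value spectrum of ``BA_hat``: the
first ``M`` singular values stand clear of the rest.  Because noise makes
no singular value exactly zero, the cut is placed at the largest
consecutive-ratio gap (a scree criterion).  The whole procedure is
iterated — infer M, refit at that M, re-infer — until M is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeQTLModel
from .models import FitOptions, fit_geqtl, init_C_lasso, _ridge_pinv_right

__all__ = ["RankDiagnostics", "infer_M", "iterate_M", "permutation_fdr"]


@dataclass
class RankDiagnostics:
    """Spectrum and decision of one M-inference step."""

    singular_values: np.ndarray
    chosen_M: int
    gap_ratios: np.ndarray
    iterations: int = 1
    stable: bool = True


def infer_M(
    X: np.ndarray,
    Z: np.ndarray,
    L: Optional[np.ndarray] = None,
    C: Optional[np.ndarray] = None,
    cap: int = 20,
    delta: float = 0.3,
    floor: float = 1e-10,
    ridge_scale: float = 0.1,
) -> RankDiagnostics:
    """Infer M from the singular-value gap of the group-wise estimate.

    Parameters
    ----------
    X, Z : standardized genotype and expression matrices.
    L, C : current confounder and individual-association estimates
        (defaults: zero matrices).
    cap : only ranks ``k <= cap`` are considered (M << min(K, N)).
    delta : a candidate rank ``k`` must satisfy ``s_k > delta * s_1``;
        gaps inside the noise floor are not trusted.  The decaying edge
        of the noise bulk produces large consecutive ratios among small
        singular values, so the bar is deliberately high.  Consequence:
        group factors weaker than ``delta`` times the strongest are not
        counted — the procedure targets the regime where the few true
        group effects have comparable scales.
    floor : singular values below ``floor * s_1`` count as numerically
        zero; if all are, ``M = 0`` with ``stable = False``.
    ridge_scale : ridge added to ``X X^T`` before inversion, as a
        fraction of its mean eigenvalue.  When the number of SNPs
        approaches the number of samples the plain inverse amplifies
        noise along near-null genotype directions and buries the
        spectral gap; a ridge at a tenth of the mean eigenvalue damps
        those directions while barely shrinking well-conditioned signal.

    The chosen ``M`` maximizes the ratio ``s_k / s_{k+1}`` over admissible
    ``k`` — a deterministic, scale-free reading of "the first k singular
    values are large and clearly separated from the (k+1)-th".
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    if L is None:
        L = np.zeros_like(Z)
    if C is None:
        C = np.zeros((Z.shape[0], X.shape[0]))
    BA_hat = (Z - L - C @ X) @ _ridge_pinv_right(X, eps_scale=ridge_scale)
    s = np.linalg.svd(BA_hat, compute_uv=False)
    if s.size == 0 or s[0] <= 0 or not np.isfinite(s[0]):
        return RankDiagnostics(s, 0, np.array([]), stable=False)
    eff_rank = int(np.sum(s > floor * s[0]))
    kmax = min(cap, eff_rank, s.size - 1)
    if kmax < 1:
        return RankDiagnostics(s, 0, np.array([]), stable=False)
    with np.errstate(divide="ignore"):
        ratios = s[:kmax] / np.maximum(s[1 : kmax + 1], floor * s[0])
    admissible = s[:kmax] > delta * s[0]
    if not admissible.any():
        return RankDiagnostics(s, 0, ratios, stable=False)
    ratios_adm = np.where(admissible, ratios, -np.inf)
    chosen = int(np.argmax(ratios_adm)) + 1
    # a gap barely above 1 means no clear separation (e.g. pure noise):
    # report the best guess but flag it as unstable
    stable = bool(ratios_adm[chosen - 1] >= 1.5)
    return RankDiagnostics(s, chosen, ratios, stable=stable)


def iterate_M(
    X: np.ndarray,
    Z: np.ndarray,
    fit_options: Optional[FitOptions] = None,
    max_outer: int = 5,
    alpha: float = 0.2,
    beta: float = 0.2,
    gamma: float = 0.3,
    rho: float = 2.0,
    variant: str = "geqtl",
    mask=None,
    cap: int = 20,
    delta: float = 0.3,
    ridge_scale: float = 0.1,
    init_eta: Optional[float] = None,
    fit_kwargs: Optional[dict] = None,
) -> tuple[int, Optional[GeQTLModel], RankDiagnostics]:
    """Iteratively refine M: lasso-init C, infer M, refit, re-infer.

    Starts from a light lasso estimate of ``C`` (with ``L = 0``), infers
    M from the singular-value gap, fits a geQTL model at that M, then
    re-infers M from the fitted ``C`` and ``L``.  Stops when M repeats
    between consecutive rounds or ``max_outer`` is reached.  If M
    oscillates between values the smaller one is returned with
    ``stable = False`` on the diagnostics.

    Returns ``(M, model, diagnostics)``; ``model`` is ``None`` only if
    the first inference already yields ``M = 0``.
    """
    if max_outer < 1:
        raise ValueError("max_outer must be >= 1")
    fit_options = fit_options or FitOptions()
    fit_kwargs = dict(fit_kwargs or {})
    hyper = dict(alpha=alpha, beta=beta, gamma=gamma, rho=rho)
    hyper.update(fit_kwargs)

    C0 = init_C_lasso(np.asarray(X, float), np.asarray(Z, float), eta=init_eta)
    diag = infer_M(X, Z, L=None, C=C0, cap=cap, delta=delta, ridge_scale=ridge_scale)
    M = diag.chosen_M
    model: Optional[GeQTLModel] = None
    history = [M]
    for outer in range(max_outer):
        if M == 0:
            diag.stable = False
            break
        model = fit_geqtl(
            X, Z, M, hyper["alpha"], hyper["beta"], hyper["gamma"], hyper["rho"],
            variant=variant, options=fit_options, mask=mask,
        )
        diag = infer_M(
            X, Z, L=model.L, C=model.C, cap=cap, delta=delta, ridge_scale=ridge_scale
        )
        diag.iterations = outer + 1
        M_new = diag.chosen_M
        if M_new == M:
            break
        if M_new in history:  # oscillation: settle on the smaller value
            M = min(M, M_new)
            diag.stable = False
            diag.chosen_M = M
            break
        history.append(M_new)
        M = M_new
    return M, model, diag


def permutation_fdr(
    X: np.ndarray,
    Z: np.ndarray,
    fit_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n_perm: int = 50,
    threshold_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate the FDR of association calls by sample permutation.

    ``fit_fn(X, Z)`` must return an ``N x K`` association-weight matrix.
    For each permutation the sample columns of ``X`` are shuffled —
    severing every SNP-gene link while preserving each matrix's internal
    structure — and the model is refit.  For each threshold ``t``,

        FDR(t) = mean permuted #{|w| > t} / observed #{|w| > t}

    clipped to [0, 1] and monotonized to be non-increasing in ``t``.
    Thresholds with no observed calls get ``NaN``.

    Returns a DataFrame with columns ``threshold``, ``observed``,
    ``expected_null``, ``fdr``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    obs = np.abs(np.asarray(fit_fn(X, Z), float))
    if threshold_grid is None:
        q = np.quantile(obs[obs > 0], np.linspace(0.0, 0.99, 25)) if (obs > 0).any() else [0.0]
        threshold_grid = np.unique(np.concatenate([[0.0], q]))
    thresholds = np.asarray(sorted(threshold_grid))

    null_counts = np.zeros((n_perm, thresholds.size))
    for p in range(n_perm):
        Xp = X[:, rng.permutation(X.shape[1])]
        wp = np.abs(np.asarray(fit_fn(Xp, Z), float))
        null_counts[p] = [(wp > t).sum() for t in thresholds]

    observed = np.array([(obs > t).sum() for t in thresholds], float)
    expected = null_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, np.clip(expected / observed, 0.0, 1.0), np.nan)
    # monotonize: FDR must not increase with a stricter threshold
    running = np.inf
    for i in range(fdr.size):
        if np.isnan(fdr[i]):
            continue
        fdr[i] = min(fdr[i], running)
        running = fdr[i]
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "observed": observed,
            "expected_null": expected,
            "fdr": fdr,
        }
    )
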