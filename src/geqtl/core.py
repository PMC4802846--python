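"""Shared numerical primitives and model containers.

This module holds the pieces every fitting routine needs: row
standardization of genotype/expression matrices, the singular-value
soft-thresholding (SVT) operator that is the proximal map of the nuclear
norm, and evaluation of the penalized least-squares objective used by the
geQTL family of models.

Conventions
-----------
Matrices follow the eQTL-mapping layout: the genotype matrix ``X`` is
``K x H`` (SNPs by samples, coded 0/1/2 before standardization) and the
expression matrix ``Z`` is ``N x H`` (genes by samples).  Rows are
standardized to zero mean and *unit sum of squares*, so that ``Z @ X.T``
is exactly the gene-SNP Pearson correlation matrix.  All model
coefficients are reported on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "GeQTLModel",
    "BaselineModel",
    "standardize",
    "svt",
    "nuclear_norm",
    "geqtl_loss",
    "objective",
]


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Standardize each row to zero mean and unit sum of squares.

    With this scaling the cross-product of two standardized rows is their
    Pearson correlation, which makes correlation screening (``|Z @ X.T|``)
    exact rather than approximate.

    Parameters
    ----------
    matrix : ndarray of shape (R, H)
        Rows are variables (SNPs or genes), columns are samples. ``H >= 2``.

    Returns
    -------
    ndarray of shape (R, H)
        Row-standardized copy.

    Raises
    ------
    ValueError
        If a row is constant (zero variance); the message names the row.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("expected a 2-d matrix with at least 2 samples")
    centered = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"zero variance: row {bad[0]} is constant and cannot be standardized"
        )
    return centered / norms[:, None]


def svt(O: np.ndarray, lam: float) -> np.ndarray:
    """Singular-value soft-thresholding operator ``H_lam``.

    Computes ``U @ diag((d_i - lam)_+) @ V.T`` from the SVD
    ``O = U @ diag(d) @ V.T``.  This is the unique minimizer of

        (1/2) ||O - S||_F^2 + lam * ||S||_*

    i.e. the proximal operator of the nuclear norm — the exact update for
    the low-rank confounder matrix ``L``.  Singular values equal to
    ``lam`` shrink to zero.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    O = np.asarray(O, dtype=float)
    if not np.all(np.isfinite(O)):
        raise ValueError("svt: input contains non-finite entries")
    if lam == 0:
        return O.copy()
    U, d, Vt = np.linalg.svd(O, full_matrices=False)
    d_shrunk = np.maximum(d - lam, 0.0)
    nz = d_shrunk > 0
    if not np.any(nz):
        return np.zeros_like(O)
    return (U[:, nz] * d_shrunk[nz]) @ Vt[nz]


def nuclear_norm(M: np.ndarray) -> float:
    """Sum of singular values of ``M``."""
    return float(np.linalg.svd(M, compute_uv=False).sum())


def geqtl_loss(
    Z: np.ndarray,
    L: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
) -> float:
    """Squared Frobenius residual ``||Z - L - (B A + C) X||_F^2``.

    ``B @ A`` carries the rank-``M`` group-wise associations, ``C`` the
    individual SNP-gene associations, and ``L`` the low-rank confounder
    component.  Zero exactly when the model reproduces ``Z``.
    """
    Z = np.asarray(Z, float)
    X = np.asarray(X, float)
    if Z.shape[1] != X.shape[1]:
        raise ValueError(
            f"sample mismatch: Z has {Z.shape[1]} samples, X has {X.shape[1]}"
        )
    R = Z - L - (B @ A + C) @ X
    return float(np.sum(R * R))


@dataclass
class _Labeled:
    """Labeled matrix base: rows are features, columns are samples."""

    values: np.ndarray
    row_ids: Sequence[str]
    sample_ids: Sequence[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length does not match values")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match values")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GenotypeMatrix(_Labeled):
    """``K x H`` SNP matrix, entries coded 0/1/2 before standardization."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.standardized:
            if not np.isin(self.values, (0.0, 1.0, 2.0)).all():
                raise ValueError("raw genotype entries must be coded 0/1/2")

    @property
    def snp_ids(self) -> Sequence[str]:
        return self.row_ids

    def standardize(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            standardize(self.values), list(self.row_ids), list(self.sample_ids), True
        )


@dataclass
class ExpressionMatrix(_Labeled):
    """``N x H`` gene-expression matrix, continuous traits."""

    @property
    def gene_ids(self) -> Sequence[str]:
        return self.row_ids

    def standardize(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            standardize(self.values), list(self.row_ids), list(self.sample_ids), True
        )


@dataclass
class BaselineModel:
    """Fitted Lasso (``L is None``) or LORS baseline.

    ``W`` is the full ``N x K`` association-weight matrix; for LORS, ``L``
    is the low-rank confounder estimate.
    """

    W: np.ndarray
    L: Optional[np.ndarray] = None
    hyperparams: dict = field(default_factory=dict)
    objective_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return self.W


@dataclass
class GeQTLModel:
    """Fitted geQTL model: the quadruple ``(A, B, C, L)``.

    ``A`` (``M x K``) maps SNPs to ``M`` latent group factors, ``B``
    (``N x M``) maps factors to genes, ``C`` (``N x K``) holds individual
    associations, and ``L`` (``N x H``) absorbs confounder variation.
    ``variant`` is one of ``"geqtl"``, ``"geqtl_plus"``, ``"geqtl_ridge"``;
    the latter two restrict the support of ``C`` to a screening mask.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    L: np.ndarray
    hyperparams: dict
    M: int
    variant: str = "geqtl"
    objective_trace: list = field(default_factory=list)
    block_trace: list = field(default_factory=list)
    converged: bool = True
    n_sweeps: int = 0

    @property
    def weights(self) -> np.ndarray:
        """Total association matrix ``B @ A + C`` (group-wise + individual)."""
        return self.B @ self.A + self.C

    @property
    def group_weights(self) -> np.ndarray:
        return self.B @ self.A


def objective(model, X: np.ndarray, Z: np.ndarray) -> float:
    """Penalized objective of a fitted or initialized model.

    For the geQTL family this is

        ||Z - L - (B A + C) X||_F^2 + rho ||L||_* + alpha ||A||_1
            + beta ||B||_1 + gamma ||C||_1

    with the ``C`` penalty replaced by ``gamma ||C||_2^2`` for the ridge
    variant.  For baselines it is the Lasso/LORS objective.
    """
    if isinstance(model, BaselineModel):
        hp = model.hyperparams
        L = model.L if model.L is not None else np.zeros_like(Z)
        R = Z - model.W @ X - L
        val = float(np.sum(R * R)) + hp.get("eta", 0.0) * float(
            np.abs(model.W).sum()
        )
        if model.L is not None:
            val += hp.get("rho", 0.0) * nuclear_norm(model.L)
        return val
    hp = model.hyperparams
    val = geqtl_loss(Z, model.L, model.A, model.B, model.C, X)
    val += hp.get("rho", 0.0) * nuclear_norm(model.L)
    val += hp.get("alpha", 0.0) * float(np.abs(model.A).sum())
    val += hp.get("beta", 0.0) * float(np.abs(model.B).sum())
    if model.variant == "geqtl_ridge":
        val += hp.get("gamma", 0.0) * float(np.sum(model.C**2))
    else:
        val += hp.get("gamma", 0.0) * float(np.abs(model.C).sum())
    return val
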