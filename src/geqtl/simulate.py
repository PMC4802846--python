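"""Synthetic eQTL data with known individual and group-wise associations.

The generator reproduces the structure of the benchmark simulation used
throughout this package's evaluation: a ``K x H`` genotype matrix of
0/1/2-coded SNPs, a ground-truth coefficient matrix ``beta`` made of a
handful of rectangular group blocks (a set of SNPs jointly regulating a
set of genes) plus a cis diagonal of individual signals, a low-rank
confounder term, and i.i.d. Gaussian noise:

    Z[j, :] = beta[j, :] @ X + Xi[j, :] + E[j, :]

with ``E[j, :] ~ N(0, phi * I)`` and each confounder row
``Xi[j, :] ~ N(0, tau * F @ F.T)`` where ``F`` is ``H x J`` with standard
normal entries (J hidden factors shared by all genes).

Defaults follow the reference simulation design: K = N = H = 100, four
group blocks of differing scales, association strength 1, phi = 0.1,
tau = 0.1, J = 10, plus the cis diagonal.  The signal-to-noise ratio is
``SNR = sqrt(Var(beta X) / Var(Xi + E))`` and is controlled through
``phi``; :func:`calibrate_phi` searches ``phi`` for a requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_genotypes",
    "make_truth",
    "make_expression",
    "snr",
    "simulate_dataset",
    "calibrate_phi",
    "write_dataset",
]

#: Default group-block geometry: (snp_start, gene_start, n_snps, n_genes)
#: for four blocks of differing scales, placed off the cis diagonal and
#: pairwise disjoint in both SNP and gene index ranges.
DEFAULT_BLOCKS: Tuple[Tuple[int, int, int, int], ...] = (
    (0, 30, 10, 10),
    (15, 55, 15, 15),
    (35, 75, 20, 20),
    (60, 0, 25, 25),
)


@dataclass
class SimConfig:
    """Parameters of one synthetic eQTL dataset."""

    K: int = 100
    N: int = 100
    H: int = 100
    blocks: Sequence[Tuple[int, int, int, int]] = DEFAULT_BLOCKS
    assoc_strength: float = 1.0
    phi: float = 0.1
    tau: float = 0.1
    J: int = 10
    cis_diagonal: bool = True
    maf_range: Tuple[float, float] = (0.05, 0.5)
    allow_overlap: bool = False
    seed: Optional[int] = None

    @property
    def n_groups(self) -> int:
        return len(self.blocks)

    def validate(self) -> None:
        if self.K < 1 or self.N < 1 or self.H < 1:
            raise ValueError("K, N, H must all be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.phi < 0 or self.tau < 0:
            raise ValueError("phi and tau must be nonnegative")
        for s0, g0, ws, wg in self.blocks:
            if min(s0, g0, ws, wg) < 0 or s0 + ws > self.K or g0 + wg > self.N:
                raise ValueError(
                    f"block ({s0}, {g0}, {ws}, {wg}) does not fit the K x N grid"
                )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``beta`` is the ``N x K`` coefficient matrix whose support labels the
    true associations for ROC evaluation; ``group_blocks`` records each
    block as ``(snp_indices, gene_indices)``.  The realized confounder
    loadings ``F``, confounder effect ``Xi``, and noise ``E`` are stored
    so that ``beta @ X + Xi + E`` reproduces ``Z`` bitwise.
    """

    beta: np.ndarray
    group_blocks: List[Tuple[np.ndarray, np.ndarray]]
    F: Optional[np.ndarray] = None
    Xi: Optional[np.ndarray] = None
    E: Optional[np.ndarray] = None
    snr: Optional[float] = None

    @property
    def support(self) -> np.ndarray:
        """Binary ``N x K`` matrix of true associations."""
        return (self.beta != 0).astype(int)


def make_genotypes(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Draw a ``K x H`` genotype matrix of independent binomial(2, maf) SNPs.

    Each SNP gets its own minor-allele frequency, uniform on
    ``config.maf_range``.  SNPs are unlinked; this stands in for sampling
    markers from a real panel and keeps the generator self-contained.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.K)
    G = rng.binomial(2, mafs[:, None], size=(config.K, config.H)).astype(float)
    snp_ids = [f"snp{i:04d}" for i in range(config.K)]
    sample_ids = [f"s{h:04d}" for h in range(config.H)]
    return GenotypeMatrix(G, snp_ids, sample_ids, standardized=False)


def make_truth(config: SimConfig) -> SimTruth:
    """Build the ground-truth coefficient matrix: group blocks + cis diagonal.

    Every cell of every block and (if enabled) every diagonal cell gets
    value ``assoc_strength``.  Blocks must be pairwise disjoint in both
    axes unless ``allow_overlap`` is set.
    """
    config.validate()
    beta = np.zeros((config.N, config.K))
    group_blocks: List[Tuple[np.ndarray, np.ndarray]] = []
    used_snps: set = set()
    used_genes: set = set()
    for s0, g0, ws, wg in config.blocks:
        snps = np.arange(s0, s0 + ws)
        genes = np.arange(g0, g0 + wg)
        if not config.allow_overlap:
            if used_snps & set(snps) or used_genes & set(genes):
                raise ValueError(
                    f"block ({s0}, {g0}, {ws}, {wg}) overlaps another block; "
                    "set allow_overlap=True to permit this"
                )
        used_snps |= set(snps)
        used_genes |= set(genes)
        beta[np.ix_(genes, snps)] = config.assoc_strength
        group_blocks.append((snps, genes))
    if config.cis_diagonal:
        d = min(config.N, config.K)
        beta[np.arange(d), np.arange(d)] = config.assoc_strength
    return SimTruth(beta=beta, group_blocks=group_blocks)


def make_expression(
    X: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Generate ``Z = beta X + Xi + E`` and store the realized components.

    One ``H x J`` loading matrix ``F`` is drawn per dataset; each gene's
    confounder row is an independent draw from ``N(0, tau * F F^T)``, and
    the noise is i.i.d. ``N(0, phi)``.  The components are written back
    into ``truth`` so the decomposition can be checked and the realized
    SNR computed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, H = config.N, config.H
    if X.values.shape != (config.K, H):
        raise ValueError("genotype matrix shape does not match config")
    signal = truth.beta @ X.values

    F = rng.standard_normal((H, config.J))
    if config.tau > 0 and config.J > 0:
        # Xi rows ~ N(0, tau F F^T): draw G ~ N(0, I_J) per gene, Xi = sqrt(tau) G F^T
        G = rng.standard_normal((N, config.J))
        Xi = np.sqrt(config.tau) * G @ F.T
    else:
        Xi = np.zeros((N, H))
    E = (
        np.sqrt(config.phi) * rng.standard_normal((N, H))
        if config.phi > 0
        else np.zeros((N, H))
    )
    Z = signal + Xi + E

    truth.F = F
    truth.Xi = Xi
    truth.E = E
    truth.snr = snr(truth, X) if (Xi + E).var() > 0 else None

    gene_ids = [f"gene{j:04d}" for j in range(N)]
    return ExpressionMatrix(Z, gene_ids, list(X.sample_ids), standardized=False)


def _row_var(M: np.ndarray) -> float:
    """Mean over rows of the per-row (across-sample) variance."""
    return float(M.var(axis=1).mean())


def snr(truth: SimTruth, X: GenotypeMatrix) -> float:
    """Realized signal-to-noise ratio ``sqrt(Var(beta X) / Var(Xi + E))``.

    Both variances are taken per gene across samples and averaged over
    genes.  For the zero-mean noise this coincides with the pooled
    variance; for the signal it excludes the between-gene offsets that
    raw 0/1/2 genotype coding induces (each gene's mean expression
    shifts by ``sum(beta) * mean genotype``), which standardization
    removes before fitting and which therefore carry no usable
    association signal.
    """
    if truth.Xi is None or truth.E is None:
        raise ValueError("truth has no realized noise components")
    noise_var = _row_var(truth.Xi + truth.E)
    if noise_var == 0:
        raise ValueError("zero noise variance: SNR undefined")
    signal_var = _row_var(truth.beta @ X.values)
    return float(np.sqrt(signal_var / noise_var))


def simulate_dataset(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> Tuple[GenotypeMatrix, ExpressionMatrix, SimTruth]:
    """Generate one complete dataset ``(X, Z, truth)`` from a config.

    A single RNG seeded by ``seed`` (or ``config.seed``) drives genotypes,
    confounders and noise, so a fixed seed reproduces the dataset exactly.
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = _replace_seed(config, seed)
    rng = np.random.default_rng(config.seed)
    X = make_genotypes(config, rng)
    truth = make_truth(config)
    Z = make_expression(X, truth, config, rng)
    return X, Z, truth


def _replace_seed(config: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


def calibrate_phi(
    target_snr: float,
    config: Optional[SimConfig] = None,
    n_reps: int = 5,
    seed: int = 0,
) -> float:
    """Find the noise variance ``phi`` that yields a requested mean SNR.

    Because ``Var(Xi)`` is fixed by ``tau`` and ``J``, the noise variance
    decomposes as ``Var(Xi) + phi`` and the calibration is a one-line
    moment match: estimate ``Var(beta X)`` and ``Var(Xi)`` over ``n_reps``
    replicates, then solve ``target = sqrt(Var(beta X) / (Var(Xi) + phi))``
    for ``phi``.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(seed)
    sig_vars, xi_vars = [], []
    for _ in range(n_reps):
        sub = _replace_seed(config, int(rng.integers(2**31 - 1)))
        X, Z, truth = simulate_dataset(sub)
        sig_vars.append(_row_var(truth.beta @ X.values))
        xi_vars.append(_row_var(truth.Xi))
    sig, xi = float(np.mean(sig_vars)), float(np.mean(xi_vars))
    phi = sig / target_snr**2 - xi
    if phi <= 0:
        raise ValueError(
            f"target SNR {target_snr} unreachable: confounder variance alone "
            f"({xi:.3g}) already exceeds the required noise level"
        )
    return phi


def write_dataset(
    outdir,
    X: GenotypeMatrix,
    Z: ExpressionMatrix,
    truth: SimTruth,
    config: SimConfig,
) -> None:
    """Write X, Z and the truth matrix as TSV plus a config sidecar (JSON)."""
    import json

    from .io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(outdir / "X.tsv", X.values, X.row_ids, X.sample_ids)
    write_matrix(outdir / "Z.tsv", Z.values, Z.row_ids, Z.sample_ids)
    write_matrix(outdir / "beta_truth.tsv", truth.beta, Z.row_ids, X.row_ids)
    sidecar = {
        "K": config.K,
        "N": config.N,
        "H": config.H,
        "blocks": [list(b) for b in config.blocks],
        "assoc_strength": config.assoc_strength,
        "phi": config.phi,
        "tau": config.tau,
        "J": config.J,
        "cis_diagonal": config.cis_diagonal,
        "maf_range": list(config.maf_range),
        "seed": config.seed,
        "realized_snr": truth.snr,
    }
    (outdir / "config.json").write_text(json.dumps(sidecar, indent=2) + "\n")
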