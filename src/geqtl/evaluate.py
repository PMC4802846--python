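"""Evaluation metrics: partial ROC/AUC and cross-study reproducibility.

For simulated data with known truth, performance is measured by sweeping
a threshold over the absolute association weights ``|B A + C|`` (or
``|W|`` for baselines) and tracing the true-positive rate against the
false-positive rate per gene-SNP cell.  Because an eQTL caller operates
at very low tolerated FPR, the curve is evaluated on ``FPR in [0, cap]``
(default cap 0.1) and summarized by the unnormalized trapezoidal area
under that restricted range.

For pairs of studies without ground truth, two overlap statistics are
provided: the fraction of shared associations among each study's top-T
calls, and the overlap of top-T regulatory hotspots (SNPs ranked by how
many genes they are called against).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "roc", "top_assoc_overlap", "hotspot_overlap"]


@dataclass
class RocResult:
    """Partial ROC curve restricted to ``fpr <= fpr_cap``."""

    fpr: np.ndarray
    tpr: np.ndarray
    partial_auc: float
    fpr_cap: float = 0.1


def roc(
    weights: np.ndarray,
    truth_support: np.ndarray,
    fpr_cap: float = 0.1,
) -> RocResult:
    """Cell-wise ROC of ``|weights|`` against a binary truth matrix.

    All cells sharing the same absolute weight enter the confusion table
    together (a step curve), and the partial AUC is the trapezoidal area
    of the curve restricted to ``[0, fpr_cap]`` — so a perfect ranking
    scores ``fpr_cap``, and random weights score about ``fpr_cap^2 / 2``.
    """
    if not (0 < fpr_cap <= 1):
        raise ValueError("fpr_cap must lie in (0, 1]")
    w = np.abs(np.asarray(weights, float)).ravel()
    y = np.asarray(truth_support).ravel().astype(int)
    if w.shape != y.shape:
        raise ValueError("weights and truth_support shapes differ")
    if y.min() == y.max():
        raise ValueError("truth must contain both positives and negatives")
    if np.ptp(w) == 0:
        # constant weights: a single operating point (everything called)
        tpr_pt = 1.0
        return RocResult(
            fpr=np.array([0.0, fpr_cap]),
            tpr=np.array([tpr_pt, tpr_pt]),
            partial_auc=fpr_cap * tpr_pt,
            fpr_cap=fpr_cap,
        )
    fpr, tpr, _ = roc_curve(y, w, drop_intermediate=False)
    # restrict to [0, cap], interpolating the crossing point
    tpr_cap = float(np.interp(fpr_cap, fpr, tpr))
    keep = fpr <= fpr_cap
    fpr_r = np.append(fpr[keep], fpr_cap)
    tpr_r = np.append(tpr[keep], tpr_cap)
    pauc = float(np.trapezoid(tpr_r, fpr_r))
    return RocResult(fpr=fpr_r, tpr=tpr_r, partial_auc=pauc, fpr_cap=fpr_cap)


def top_assoc_overlap(
    list1: Sequence[Tuple],
    list2: Sequence[Tuple],
    T: int,
) -> float:
    """Reproducibility of associations: ``|top_T(L1) ∩ top_T(L2)| / T``.

    Inputs are (gene, SNP) pair sequences already ranked by significance
    (strongest first), e.g. by descending ``|weight|``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if T > min(len(list1), len(list2)):
        raise ValueError("T exceeds the length of a ranked list")
    top1 = set(map(tuple, list(list1)[:T]))
    top2 = set(map(tuple, list(list2)[:T]))
    return len(top1 & top2) / T


def rank_associations(
    weights: np.ndarray,
    gene_ids: Sequence[str],
    snp_ids: Sequence[str],
) -> list:
    """Rank (gene, SNP) pairs by descending ``|weight|`` (stable on ties)."""
    w = np.abs(np.asarray(weights, float))
    order = np.argsort(-w, axis=None, kind="stable")
    genes, snps = np.unravel_index(order, w.shape)
    return [(gene_ids[g], snp_ids[s]) for g, s in zip(genes, snps)]


def hotspot_overlap(
    assoc1: Iterable[Tuple],
    assoc2: Iterable[Tuple],
    T: int,
) -> float:
    """Reproducibility of regulatory hotspots: ``|top_T(S1) ∩ top_T(S2)| / T``.

    Each input is the set of significant (gene, SNP) pairs called in one
    study.  A SNP's *regulatory degree* is the number of genes it is
    called against; SNPs are ranked by descending degree (ties broken by
    SNP identifier for determinism) and the top-T sets compared.
    """
    if T <= 0:
        raise ValueError("T must be positive")

    def top_snps(assoc) -> set:
        degree: dict = {}
        for gene, snp in assoc:
            degree[snp] = degree.get(snp, 0) + 1
        if T > len(degree):
            raise ValueError("T exceeds the number of SNPs with any call")
        ranked = sorted(degree.items(), key=lambda kv: (-kv[1], str(kv[0])))
        return {snp for snp, _ in ranked[:T]}

    return len(top_snps(assoc1) & top_snps(assoc2)) / T
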