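"""Simulate a benchmark eQTL dataset and fit the geQTL model.

Generates 100 SNPs x 100 genes x 100 samples with four planted
group-wise association blocks plus a cis diagonal, fits geQTL at M = 4,
and reports how well the recovered association matrix B A + C matches
the planted signals.
"""

import warnings

import numpy as np

import geqtl

warnings.simplefilter("ignore")

X, Z, truth = geqtl.simulate_dataset(geqtl.SimConfig(seed=1))
print(f"dataset: {X.shape[0]} SNPs x {Z.shape[0]} genes x {X.shape[1]} samples, "
      f"realized SNR = {truth.snr:.2f}")

Xs, Zs = geqtl.standardize(X.values), geqtl.standardize(Z.values)
model = geqtl.fit_geqtl(Xs, Zs, M=4, alpha=0.2, beta=0.2, gamma=0.3, rho=2.0,
                        options=geqtl.FitOptions(max_sweeps=60, tol=1e-9))

W = model.weights  # total associations: group-wise B A + individual C
result = geqtl.roc(W, truth.support, fpr_cap=0.1)
print(f"converged in {model.n_sweeps} sweeps, final objective "
      f"{model.objective_trace[-1]:.3f}")
print(f"partial AUC on FPR in [0, 0.1]: {result.partial_auc:.4f} "
      f"(perfect = 0.1, chance = 0.005)")

# where does the signal live? group part should carry the blocks,
# individual part the cis diagonal
BA = model.group_weights
diag_share = np.abs(np.diag(model.C)).sum() / max(np.abs(model.C).sum(), 1e-12)
print(f"rank of fitted group-wise part: "
      f"{np.linalg.matrix_rank(BA, tol=1e-8)} (4 blocks planted)")
print(f"share of |C| mass on the cis diagonal: {diag_share:.2f} "
      f"(the diagonal holds the planted individual signals)")
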