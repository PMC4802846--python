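"""Estimate the false discovery rate of association calls by permutation.

Sample columns of the genotype matrix are shuffled (breaking every
SNP-gene link while preserving each matrix's internal correlation
structure), the model is refit, and the null exceedance counts give
FDR(t) = E[null #{|w| > t}] / observed #{|w| > t} for a grid of weight
thresholds.
"""

import warnings

import geqtl

warnings.simplefilter("ignore")

config = geqtl.SimConfig(K=40, N=40, H=60, blocks=((4, 20, 8, 8),),
                         phi=0.3, tau=0.1, J=3, seed=3)
X, Z, truth = geqtl.simulate_dataset(config)
Xs, Zs = geqtl.standardize(X.values), geqtl.standardize(Z.values)

table = geqtl.permutation_fdr(
    Xs, Zs, lambda x, z: geqtl.fit_lasso(x, z, 0.1).W, n_perm=20, seed=0
)
rows = table.dropna(subset=["fdr"]).iloc[::6]
print("threshold  observed  expected_null  FDR")
for _, r in rows.iterrows():
    print(f"{r.threshold:9.4f}  {int(r.observed):8d}  {r.expected_null:13.1f}  {r.fdr:.3f}")
print("high thresholds keep only calls that permutations almost never reach;")
print("pick the threshold where the FDR column crosses your target (e.g. 0.01)")
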