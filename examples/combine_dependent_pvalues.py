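"""Combine a handful of dependent p-values with the weighted Lancaster test.

Three genes contribute five tests; the tests within gene A are positively
correlated, which the supplied transformed-scale covariance encodes.  The
naive chi-square reference ignores that correlation and overstates the
evidence; the moment-adjusted methods correct for it.
"""

import numpy as np

from lancaster import (
    CovarianceEstimate,
    PValueVector,
    WeightVector,
    combine_pvalues,
    weights_from_gene_sizes,
)

pvals = PValueVector.from_arrays(
    [0.011, 0.028, 0.019, 0.40, 0.73],
    ids=["snp1", "snp2", "snp3", "snp4", "snp5"],
    gene_ids=["A", "A", "A", "B", "C"],
)
# gene sizes per test: the three gene-A tests share n=3, so w = 2/3 each
weights = weights_from_gene_sizes([3, 3, 3, 1, 1], scheme="inv")

# transformed-scale covariances: the gene-A pairs covary, the rest do not
rho = np.zeros((5, 5))
for i in range(3):
    for j in range(3):
        if i != j:
            rho[i, j] = 0.9  # cov of the gamma-transformed values

res = combine_pvalues(pvals, WeightVector.from_array(weights.w), CovarianceEstimate.given(rho))

print(f"T = {res.T:.4f}, E(T) = {res.moments.mean:.4f}, Var(T) = {res.moments.variance:.4f}")
print(f"Satterthwaite scaling c = {res.params.c:.4f}, df v = {res.params.v:.4f}")
for name, p in res.pvalues.items():
    print(f"  {name:12s} p = {p:.5f}")
print(
    "\nThe 'independent' row is the naive chi-square reference; the adjusted"
    "\nmethods (TA-TE) give larger, honest p-values because the three small"
    "\ngene-A p-values are correlated and partly reflect one signal."
)
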