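"""Accuracy of the tail approximations under a known correlation structure.

Draws dependent p-values through a Gaussian copula with compound-symmetric
blocks (rho = 0.3), forms the Lancaster statistic, and compares empirical
quantiles with the quantiles implied by each approximation using the exact
(quadrature) transformed-scale covariance.  The naive chi-square reference
is visibly under-dispersed in the upper tail; the adjusted methods track
the empirical distribution.
"""

import numpy as np

from lancaster import SigmaSpec, WeightVector, qq_comparison

spec = SigmaSpec(kind="block_fixed", rho=0.3, n_blocks=4, block_size=5)
w = WeightVector.from_array(np.full(spec.dim, 2.0))
table = qq_comparison(spec, w, n_draws=30_000, seed=21, probs=[0.5, 0.9, 0.95, 0.99])

print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
ex = table[table["prob"] == 0.95].iloc[0]
print(
    f"\nAt the 95th percentile the empirical quantile is {ex['empirical']:.1f} while"
    f"\nthe naive chi-square reference puts it at {ex['naive']:.1f} - so the naive test"
    f"\nrejects too often.  The adjusted quantiles (TA..TE) sit within Monte-Carlo"
    f"\nnoise of the empirical curve."
)
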