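"""Estimate the transformed-scale covariance of dependent tests by permutation.

Simulates a small pathway with strong LD, runs the per-variant score test
under many phenotype shuffles (genotype rows fixed, preserving LD) and
reports the covariance of the gamma-transformed values — the quantity that
enters Var(T) of the Lancaster statistic.
"""

import numpy as np

from lancaster import (
    LDConfig,
    WeightVector,
    estimate_transformed_covariance,
    simulate_genotypes,
)

cfg = LDConfig(n_subjects=400, gene_sizes=(4, 2), D=0.20)
g = simulate_genotypes(cfg, seed=11)
y = np.random.default_rng(12).integers(0, 2, cfg.n_subjects).astype(np.int8)

w = WeightVector.from_array(np.full(6, 2.0))
est = estimate_transformed_covariance(g, y, w, tester="trend", m=2000, seed=13)

np.set_printoptions(precision=2, suppress=True)
print("transformed-scale covariance (m = 2000 permutations):")
print(est.rho)
print(
    f"\nDiagonal ~ 2w = 4 (variance of a chi-square with 2 df)."
    f"\nAdjacent gene-1 pairs (r = {0.20 / 0.21:.2f} allelic correlation) show large"
    f"\ncovariance, e.g. rho[0,1] = {est.rho[0, 1]:.2f}; across genes it is ~0,"
    f"\ne.g. rho[0,4] = {est.rho[0, 4]:.2f}.  Var(T) adds twice the upper-triangle sum."
)
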