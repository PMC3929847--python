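"""Permutation estimation of the transformed-scale covariance matrix.

The variance of the Lancaster statistic under dependence needs the pairwise
covariances ``rho_ij`` of the gamma-transformed values
``x_i = G^{-1}_{w_i/2,2}(1 - p_i)``.  When only raw data are available these
are estimated by phenotype permutation: the genotype rows are left intact
(preserving LD among variants) while the phenotype labels are shuffled
across subjects, the per-variant association test is re-run on each
shuffled dataset, and ``rho_ij`` is the sample covariance of the transformed
values across permutations.  The permutation null breaks any
genotype-phenotype association, so the estimate reflects only the
correlation among the tests themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .core import WeightVector, gamma_transform
from .ld_sim import per_variant_test

__all__ = ["CovarianceEstimate", "estimate_transformed_covariance"]


@dataclass(frozen=True)
class CovarianceEstimate:
    """Symmetric matrix of transformed-scale covariances ``rho_ij``.

    ``source`` records whether the matrix was user-supplied or estimated by
    permutation (with ``m`` permutations).  The diagonal approximates
    ``2 w_i`` under the null; only the off-diagonals enter Var(T).
    """

    rho: np.ndarray
    m: int = 0
    source: str = "given"
    seed: Optional[int] = None

    @classmethod
    def given(cls, rho: np.ndarray) -> "CovarianceEstimate":
        rho = np.asarray(rho, dtype=float)
        if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
            raise ValueError("rho must be a square matrix")
        if not np.allclose(rho, rho.T, atol=1e-10):
            raise ValueError("rho must be symmetric")
        return cls(rho=rho, m=0, source="given")


def _permutation_matrix(y: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Subjects x m matrix whose columns are independent shuffles of y."""
    out = np.empty((y.size, m), dtype=float)
    for k in range(m):
        out[:, k] = y[rng.permutation(y.size)]
    return out


def estimate_transformed_covariance(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    w: WeightVector,
    tester: str = "trend",
    m: int = 1000,
    seed=None,
) -> CovarianceEstimate:
    """Estimate ``rho_ij`` by phenotype permutation.

    Parameters
    ----------
    genotypes
        Subjects x variants numeric matrix (complete, no missing values).
    phenotype
        Binary 0/1 vector with both classes present.
    w
        Per-variant weights (chi-square degrees of freedom for the transform).
    tester
        ``trend`` (closed-form score test, vectorized across permutations) or
        ``logistic`` (per-variant logistic Wald test, markedly slower).
    m
        Number of permutations (>= 2).  Permutations are drawn uniformly and
        independently; distinctness is not enforced.
    seed
        Int, SeedSequence or Generator controlling the permutation stream;
        the estimate is deterministic given the seed.

    Returns the sample covariance matrix (ddof = 1) of the transformed
    values across the ``m`` permutations.
    """
    if m < 2:
        raise ValueError("at least 2 permutations are required")
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.ndim != 2 or g.shape[0] != y.size:
        raise ValueError("genotypes must be subjects x variants, matching phenotype length")
    if np.any(np.isnan(g)):
        raise ValueError("genotypes must be complete (no missing values)")
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("phenotype must contain both classes")
    if len(w) != g.shape[1]:
        raise ValueError("weight vector length must equal the number of variants")

    rng = np.random.default_rng(seed)
    perm = _permutation_matrix(y, m, rng)

    if tester == "trend":
        # score test vectorized over all permutations at once:
        # U = G' (y_perm - ybar), V = ybar (1 - ybar) Sxx  (both invariant
        # to the permutation since ybar and the genotype columns are fixed)
        n = g.shape[0]
        ybar = y.mean()
        xbar = g.mean(axis=0)
        sxx = (g * g).sum(axis=0) - n * xbar**2
        u = g.T @ perm - np.outer(xbar, perm.sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = u**2 / (ybar * (1.0 - ybar) * sxx)[:, None]
        pv = stats.chi2.sf(stat, 1)
        pv[sxx <= 0, :] = 1.0
    elif tester == "logistic":
        pv = np.empty((g.shape[1], m))
        for k in range(m):
            pv[:, k] = per_variant_test(g, perm[:, k], method="logistic").values
    else:
        raise ValueError(f"unknown tester {tester!r}")

    x = gamma_transform(pv, w.w[:, None])
    rho = np.cov(x, ddof=1)
    rho = np.atleast_2d(rho)
    rho = 0.5 * (rho + rho.T)  # enforce exact symmetry against float noise
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return CovarianceEstimate(rho=rho, m=m, source="permutation", seed=seed_int)
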