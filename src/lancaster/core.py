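"""Gamma-quantile transformation and moments of the weighted Lancaster statistic.

The Lancaster procedure generalizes Fisher's method: each p-value ``p_i`` is
mapped to a chi-square variable with ``w_i`` degrees of freedom through the
inverse CDF of a Gamma(w_i / 2, scale 2) distribution, and the transformed
values are summed,

    T = sum_i  G^{-1}_{w_i/2, 2}(1 - p_i).

Under independence T is exactly chi-square with ``sum_i w_i`` degrees of
freedom; with ``w_i = 2`` for every test it reduces to Fisher's
``-2 * sum_i log p_i``.  When the p-values are dependent the first moment is
unchanged, ``E(T) = sum_i w_i``, but the variance picks up the pairwise
covariances of the *transformed* values,

    Var(T) = 2 * sum_i w_i + 2 * sum_{i<j} rho_ij,

where ``rho_ij = cov(x_i, x_j)`` on the transformed (chi-square) scale.  This
module provides the transform, weight construction from gene sizes, the
statistic, and these two moments; tail approximations live in
:mod:`lancaster.approx`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "P_FLOOR",
    "PValueVector",
    "WeightVector",
    "Moments",
    "weights_from_gene_sizes",
    "gamma_transform",
    "lancaster_statistic",
    "moments_correlated",
]

#: Smallest p-value used in the transform; keeps the gamma quantile finite.
P_FLOOR = 1e-15

WEIGHT_SCHEMES = ("inv_sqrt", "inv", "flat")


@dataclass(frozen=True)
class PValueVector:
    """An ordered vector of p-values with test (and optionally gene) labels.

    Values are clipped into ``(P_FLOOR, 1]`` on construction; a p-value of
    exactly 1 is legal and transforms to 0.
    """

    values: np.ndarray
    ids: tuple
    gene_ids: Optional[tuple] = None

    @classmethod
    def from_arrays(
        cls,
        values: Sequence[float],
        ids: Optional[Sequence] = None,
        gene_ids: Optional[Sequence] = None,
    ) -> "PValueVector":
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("p-values must be a non-empty 1-D vector")
        if np.any(~np.isfinite(values)) or np.any(values <= 0) or np.any(values > 1):
            raise ValueError("p-values must lie in (0, 1]")
        values = np.clip(values, P_FLOOR, 1.0)
        if ids is None:
            ids = tuple(f"t{i}" for i in range(values.size))
        else:
            ids = tuple(ids)
            if len(ids) != values.size:
                raise ValueError("ids length does not match values")
            if len(set(ids)) != len(ids):
                raise ValueError("test ids must be unique")
        if gene_ids is not None:
            gene_ids = tuple(gene_ids)
            if len(gene_ids) != values.size:
                raise ValueError("gene_ids length does not match values")
        return cls(values=values, ids=ids, gene_ids=gene_ids)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class WeightVector:
    """Per-test chi-square degrees of freedom ``w_i > 0``.

    ``n_sizes`` optionally records the gene size each weight was derived from.
    """

    w: np.ndarray
    n_sizes: Optional[np.ndarray] = None

    @classmethod
    def from_array(cls, w: Sequence[float]) -> "WeightVector":
        w = np.asarray(w, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty 1-D vector")
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("all weights must be finite and > 0")
        return cls(w=w)

    def __len__(self) -> int:
        return self.w.size


@dataclass(frozen=True)
class Moments:
    """Mean and variance of the Lancaster statistic under dependence."""

    mean: float
    variance: float


def weights_from_gene_sizes(n_sizes: Sequence[int], scheme: str = "inv") -> WeightVector:
    """Build per-test weights from gene sizes.

    Larger genes contribute more tests to a combined statistic, which biases
    unweighted combination toward large genes.  Down-weighting each test by
    its gene's size counteracts this.

    Parameters
    ----------
    n_sizes
        Positive integer size (number of SNPs or probes) of the gene each
        test belongs to, one entry per test.
    scheme
        ``inv`` (default) gives ``w_i = 2 / n_i``, so each gene contributes
        total df 2 regardless of size; ``inv_sqrt`` gives
        ``w_i = 2 / sqrt(n_i)``; ``flat`` gives ``w_i = 2`` (plain Fisher).
        A singleton gene (``n_i = 1``) yields ``w_i = 2`` under every scheme.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")
    n = np.asarray(n_sizes, dtype=float)
    if n.ndim != 1 or n.size < 1:
        raise ValueError("gene sizes must be a non-empty 1-D vector")
    if np.any(n < 1) or np.any(n != np.floor(n)):
        raise ValueError("gene sizes must be positive integers")
    if scheme == "inv_sqrt":
        w = 2.0 / np.sqrt(n)
    elif scheme == "inv":
        w = 2.0 / n
    else:
        w = np.full(n.shape, 2.0)
    return WeightVector(w=w, n_sizes=n.astype(int))


def gamma_transform(p, w):
    """Map p-values to the upper-``p`` quantile of a chi-square with ``w`` df.

    Computes ``G^{-1}_{w/2, 2}(1 - p)``, the (1-p) quantile of a
    Gamma(shape w/2, scale 2) distribution.  Strictly decreasing in ``p``;
    ``p = 1`` maps to 0.  Inputs below ``P_FLOOR`` are clipped.  Vectorized
    over both arguments.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights (degrees of freedom) must be > 0")
    p = np.clip(p, P_FLOOR, 1.0)
    # isf(p) of chi2_w is exactly the (1-p) Gamma(w/2, 2) quantile
    x = stats.chi2.isf(p, w)
    return x if x.ndim else float(x)


def lancaster_statistic(p: PValueVector, w: WeightVector) -> float:
    """The weighted Lancaster statistic ``T = sum_i gamma_transform(p_i, w_i)``."""
    if len(p) != len(w):
        raise ValueError(f"length mismatch: {len(p)} p-values vs {len(w)} weights")
    return float(np.sum(gamma_transform(p.values, w.w)))


def _as_rho_matrix(rho, n: int) -> np.ndarray:
    """Accept None (independence), a CovarianceEstimate, or a raw matrix."""
    if rho is None:
        return np.zeros((n, n))
    rho = getattr(rho, "rho", rho)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (n, n):
        raise ValueError(f"rho must be {n}x{n}, got {rho.shape}")
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ValueError("rho must be symmetric")
    return rho


def moments_correlated(w: WeightVector, rho=None) -> Moments:
    """Mean and variance of T given transformed-scale covariances ``rho_ij``.

    ``rho`` may be ``None`` (independence), a square symmetric matrix, or a
    :class:`~lancaster.perm_cov.CovarianceEstimate`.  Only the off-diagonal
    entries enter the variance; the diagonal is fixed at ``2 w_i`` by the
    chi-square marginals.  A covariance estimate so negative that
    ``Var(T) <= 0`` is rejected rather than floored: it cannot come from a
    valid covariance matrix.
    """
    n = len(w)
    rho = _as_rho_matrix(rho, n)
    mean = float(np.sum(w.w))
    off_sum = float(np.sum(rho[np.triu_indices(n, k=1)]))
    variance = 2.0 * mean + 2.0 * off_sum
    if variance <= 0:
        raise ValueError(
            f"covariances imply Var(T) = {variance:.4g} <= 0; "
            "the supplied rho matrix is not a valid covariance estimate"
        )
    return Moments(mean=mean, variance=variance)
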