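"""Benchmarking harness: correlation structures, copula draws, Type I error / power.

Two kinds of experiment are supported.

*Distributional accuracy* (Q-Q assessment): p-values with a known
correlation structure are produced through a one-sided Gaussian copula —
``Z ~ MVN(0, Sigma)``, ``p_i = 1 - Phi(Z_i)`` — so the marginals are exactly
Uniform(0,1) while the dependence is controlled by ``Sigma``.  Empirical
quantiles of the Lancaster statistic are compared to the quantiles implied
by each tail approximation, using the *true* transformed-scale covariance
obtained by Gauss-Hermite quadrature under the copula.

*Operating characteristics* (Type I error / power): full data-level
replicates — LD genotypes, logistic phenotypes, per-variant tests,
permutation covariance, combined p-values — with the rejection proportion
at a nominal level reported per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .approx import (
    METHODS,
    combine_pvalues,
    cornish_fisher_pvalue,
    normal_approx_pvalue,
    saddlepoint_pvalue,
    satterthwaite_params,
    tail_prob_TA,
)
from .core import (
    Moments,
    PValueVector,
    WeightVector,
    gamma_transform,
    moments_correlated,
    weights_from_gene_sizes,
)
from .ld_sim import (
    DiseaseModel,
    LDConfig,
    per_variant_test,
    simulate_genotypes,
    simulate_phenotype,
    variant_gene_sizes,
)
from .perm_cov import CovarianceEstimate, estimate_transformed_covariance

__all__ = [
    "SigmaSpec",
    "ScenarioSpec",
    "build_sigma",
    "sample_correlated_pvalues",
    "copula_transformed_cov",
    "copula_rho_matrix",
    "qq_comparison",
    "rejection_rate_experiment",
]

logger = logging.getLogger(__name__)

SIGMA_KINDS = ("block_fixed", "block_beta", "block_uniform", "random_pd")


@dataclass(frozen=True)
class SigmaSpec:
    """A correlation-structure recipe for the copula experiments.

    ``block_fixed``: compound-symmetric blocks with a common correlation
    ``rho``; ``block_beta`` / ``block_uniform``: one rho per block drawn from
    Beta(0.3, 1.5) or Uniform(-0.2, 0.2); ``random_pd``: a full random
    positive-definite correlation matrix.
    """

    kind: str = "block_fixed"
    rho: float = 0.3
    n_blocks: int = 20
    block_size: int = 5

    def __post_init__(self):
        if self.kind not in SIGMA_KINDS:
            raise ValueError(f"unknown sigma kind {self.kind!r}; choose from {SIGMA_KINDS}")
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be >= 1")
        if self.kind == "block_fixed":
            lo = -1.0 / (self.block_size - 1) if self.block_size > 1 else -1.0
            if not lo < self.rho < 1.0:
                raise ValueError(
                    f"rho = {self.rho} outside the positive-definite range "
                    f"({lo:.4g}, 1) for block size {self.block_size}"
                )

    @property
    def dim(self) -> int:
        return self.n_blocks * self.block_size


def _compound_symmetric(size: int, rho: float) -> np.ndarray:
    return rho * np.ones((size, size)) + (1.0 - rho) * np.eye(size)


def build_sigma(spec: SigmaSpec, seed=None) -> np.ndarray:
    """Build a positive-definite correlation matrix from a recipe."""
    rng = np.random.default_rng(seed)
    bs, nb = spec.block_size, spec.n_blocks
    if spec.kind == "block_fixed":
        rhos = np.full(nb, spec.rho)
    elif spec.kind == "block_beta":
        rhos = rng.beta(0.3, 1.5, size=nb)
    elif spec.kind == "block_uniform":
        rhos = rng.uniform(-0.2, 0.2, size=nb)
    else:  # random_pd: random eigenvectors, Dirichlet eigenvalues, unit diagonal
        dim = spec.dim
        q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
        lam = rng.dirichlet(np.ones(dim)) * dim
        s = (q * lam) @ q.T
        d = np.sqrt(np.diag(s))
        sigma = s / np.outer(d, d)
        np.fill_diagonal(sigma, 1.0)
        return 0.5 * (sigma + sigma.T)
    lo = -1.0 / (bs - 1) if bs > 1 else -1.0
    if np.any(rhos <= lo):
        raise ValueError("drawn block correlation violates positive definiteness")
    blocks = [_compound_symmetric(bs, r) for r in rhos]
    sigma = np.zeros((spec.dim, spec.dim))
    for b, blk in enumerate(blocks):
        sigma[b * bs : (b + 1) * bs, b * bs : (b + 1) * bs] = blk
    return sigma


def _copula_pvalue_draws(sigma: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n_draws, sigma.shape[0])) @ L.T
    return stats.norm.sf(z)


def sample_correlated_pvalues(sigma: np.ndarray, seed=None, n_draws: int = 1) -> PValueVector:
    """Draw one vector of dependent p-values with exactly uniform marginals.

    For ``n_draws > 1`` use :func:`qq_comparison` or the internal batch
    sampler; this function returns the first draw as a PValueVector.
    """
    sigma = np.asarray(sigma, dtype=float)
    try:
        p = _copula_pvalue_draws(sigma, n_draws, np.random.default_rng(seed))
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma is not positive definite (Cholesky failed)") from exc
    return PValueVector.from_arrays(np.clip(p[0], 1e-300, 1.0))


def copula_transformed_cov(r: float, wi: float, wj: float, n_nodes: int = 64) -> float:
    """Transformed-scale covariance of one pair under the Gaussian copula.

    Computes ``cov(x_i, x_j)`` for ``x = gamma_transform(1 - Phi(Z))`` with
    ``corr(Z_i, Z_j) = r`` by tensor-product Gauss-Hermite quadrature; this
    is the population quantity the permutation procedure estimates.
    """
    t, wt = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * t
    wt = wt / np.sqrt(np.pi)
    fi = gamma_transform(stats.norm.sf(z), wi)
    fj = gamma_transform(stats.norm.sf(z), wj)
    if abs(r) < 1e-14:
        return 0.0
    # z_j | z_i=a  ~  N(r a, 1 - r^2): integrate f_j over the conditional law
    s = np.sqrt(1.0 - r * r)
    zz = r * z[:, None] + s * z[None, :]
    fj_cond = gamma_transform(stats.norm.sf(zz), wj) @ wt
    e_ij = float(np.sum(wt * fi * fj_cond))
    return e_ij - wi * wj


def copula_rho_matrix(sigma: np.ndarray, w: WeightVector, n_nodes: int = 64) -> np.ndarray:
    """Full transformed-scale covariance matrix under the Gaussian copula."""
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    rho = np.zeros((n, n))
    cache: Dict[Tuple[float, float, float], float] = {}
    ww = w.w
    for i in range(n):
        rho[i, i] = 2.0 * ww[i]
        for j in range(i + 1, n):
            key = (round(float(sigma[i, j]), 12), float(ww[i]), float(ww[j]))
            if key not in cache:
                cache[key] = copula_transformed_cov(sigma[i, j], ww[i], ww[j], n_nodes)
            rho[i, j] = rho[j, i] = cache[key]
    return rho


def _method_pvalue(name: str, T: float, m: Moments, params) -> float:
    if name == "independent":
        return float(stats.chi2.sf(T, m.mean))
    if name == "TA":
        return tail_prob_TA(T, params)
    if name == "TB":
        return normal_approx_pvalue(T, m, params.v, "fisher")
    if name == "TC":
        return normal_approx_pvalue(T, m, params.v, "wilson_hilferty")
    if name == "TD":
        return cornish_fisher_pvalue(T, m, params.v)
    if name == "TE":
        return saddlepoint_pvalue(T, m, params.v)
    raise ValueError(name)


def _invert_method_quantile(name: str, prob: float, m: Moments, params) -> float:
    """T such that the method's lower CDF at T equals ``prob``."""
    target = 1.0 - prob

    def f(T):
        return _method_pvalue(name, T, m, params) - target

    hi = max(4.0 * m.mean, 10.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            break
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))


def qq_comparison(
    sigma_spec: SigmaSpec,
    w: WeightVector,
    n_draws: int = 10_000,
    seed=None,
    probs: Optional[Sequence[float]] = None,
    methods: Iterable[str] = METHODS,
) -> pd.DataFrame:
    """Empirical vs approximated quantiles of T under a copula correlation structure.

    Draws ``n_draws`` correlated p-value vectors, forms the Lancaster
    statistic for each, and tabulates its empirical quantiles against the
    model quantiles implied by each approximation.  The approximations use
    the exact (quadrature) transformed-scale covariance, so discrepancies
    measure the quality of the tail approximation itself, not of the
    covariance estimate.  Returns a tidy plot-ready table.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable quantiles")
    if probs is None:
        probs = np.concatenate([np.linspace(0.05, 0.90, 18), [0.95, 0.975, 0.99, 0.995]])
    probs = np.asarray(probs, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = build_sigma(sigma_spec, rng)
    if len(w) != sigma.shape[0]:
        raise ValueError("weight vector length must match sigma dimension")
    p = _copula_pvalue_draws(sigma, n_draws, rng)
    x = gamma_transform(p, w.w[None, :])
    T_samples = x.sum(axis=1)
    emp = np.quantile(T_samples, probs)

    rho = copula_rho_matrix(sigma, w)
    m = moments_correlated(w, rho)
    params = satterthwaite_params(m)

    out = {"prob": probs, "empirical": emp}
    out["naive"] = stats.chi2.ppf(probs, m.mean)
    for name in methods:
        if name == "independent":
            continue
        out[name] = [_invert_method_quantile(name, q, m, params) for q in probs]
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell of the Type I error / power study."""

    ld_config: LDConfig
    model: DiseaseModel
    reps: int = 1000
    m_perm: int = 1000
    alpha: float = 0.05
    weighting: str = "gene_size"
    weight_scheme: str = "inv"
    tester: str = "trend"
    seed: int = 0

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.weighting not in ("gene_size", "flat"):
            raise ValueError("weighting must be 'gene_size' or 'flat'")


def scenario_weights(spec: ScenarioSpec) -> WeightVector:
    sizes = variant_gene_sizes(spec.ld_config.gene_sizes)
    scheme = spec.weight_scheme if spec.weighting == "gene_size" else "flat"
    return weights_from_gene_sizes(sizes, scheme=scheme)


def rejection_rate_experiment(
    spec: ScenarioSpec, methods: Iterable[str] = METHODS
) -> Dict[str, object]:
    """Rejection proportion at ``spec.alpha`` per combining method.

    Each replicate simulates genotypes and phenotypes, runs the per-variant
    test, estimates the transformed-scale covariance by permutation on that
    replicate's own data, and combines.  Per-replicate seeds are spawned
    from the master seed by counter, so results do not depend on execution
    order.  If only the naive independent method is requested the
    permutation step is skipped.  Replicate-level failures (e.g. a
    degenerate phenotype draw) are counted and reported, never silently
    dropped.
    """
    methods = tuple(methods)
    need_perm = any(name != "independent" for name in methods)
    w = scenario_weights(spec)
    children = np.random.SeedSequence(spec.seed).spawn(spec.reps)
    rej = {name: 0 for name in methods}
    n_ok = 0
    n_fail = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            g = simulate_genotypes(spec.ld_config, rng)
            y = simulate_phenotype(g, spec.model, rng)
            p = per_variant_test(g, y, method=spec.tester)
            if need_perm:
                rho = estimate_transformed_covariance(
                    g, y, w, tester=spec.tester, m=spec.m_perm, seed=rng
                )
            else:
                rho = None
            res = combine_pvalues(p, w, rho, methods=methods)
        except ValueError as exc:
            n_fail += 1
            logger.warning("replicate %d failed: %s", r, exc)
            continue
        n_ok += 1
        for name in methods:
            rej[name] += res.pvalues[name] < spec.alpha
        if (r + 1) % 100 == 0:
            logger.debug("replicate %d/%d done", r + 1, spec.reps)
    rates = {name: (rej[name] / n_ok if n_ok else float("nan")) for name in methods}
    return {
        "rates": rates,
        "n_replicates": spec.reps,
        "n_ok": n_ok,
        "n_failed": n_fail,
        "alpha": spec.alpha,
    }
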