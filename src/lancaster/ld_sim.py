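"""Simulation of pathway SNP genotypes under pairwise LD and logistic disease models.

Genotypes are simulated gene by gene.  Within a gene, loci form a first-order
Markov chain: the allele at locus 1 is Bernoulli(q), and each subsequent
locus is drawn conditionally on its left neighbour using the classical
two-locus conditional probabilities implied by the linkage-disequilibrium
coefficient D,

    P(A|B) = (qA qB + D) / qB,          P(a|B) = ((1-qA) qB - D) / qB,
    P(A|b) = (qA (1-qB) - D) / (1-qB),  P(a|b) = ((1-qA)(1-qB) + D) / (1-qB),

where A and B are the minor alleles at the two loci.  D is bounded by
``D_max = min(qA (1-qB), (1-qA) qB)``; at q = 0.3 both loci, D_max = 0.21 and
the induced allelic correlation is R = D / 0.21.  Genes are mutually
independent.  The default pathway has five genes of sizes 12, 8, 5, 3 and 2
(30 loci), MAF 0.3 at every locus, haploid 0/1 coding; diploid 0/1/2 coding
sums two independent haplotypes.

Disease status is Bernoulli through a logistic model without intercept,
``logit P(Y=1) = sum_k beta * (product of the k-th term's genotypes)``; six
canonical term sets (cases I-VI) place main effects and product interactions
on specific loci of the pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.special import expit

from .core import PValueVector

__all__ = [
    "DEFAULT_GENE_SIZES",
    "DISEASE_CASES",
    "LDConfig",
    "DiseaseModel",
    "ld_d_max",
    "disease_model",
    "simulate_genotypes",
    "simulate_phenotype",
    "per_variant_test",
    "trend_pvalues",
    "variant_gene_sizes",
]

#: Gene sizes of the benchmark pathway: G1(12), G2(8), G3(5), G4(3), G5(2).
DEFAULT_GENE_SIZES = (12, 8, 5, 3, 2)

#: Term sets of the six logistic disease cases.  Each term is a tuple of
#: (gene, locus) pairs, 1-based; multi-pair terms are product interactions.
DISEASE_CASES = {
    "I": [((1, 2),), ((1, 5),), ((1, 7),), ((1, 8),), ((1, 12),)],
    "II": [((2, 2),), ((2, 4),), ((2, 6),), ((3, 2),), ((3, 3),)],
    "III": [((3, 2),), ((3, 4),), ((4, 1),), ((4, 3),), ((5, 1),)],
    "IV": [((1, 1),), ((1, 3),), ((1, 7),), ((1, 8), (1, 10), (1, 11)), ((1, 12),)],
    "V": [((3, 1),), ((3, 3),), ((4, 2),), ((3, 2), (3, 4)), ((4, 3), (5, 1))],
    "VI": [((1, 2),), ((2, 2),), ((3, 3),), ((5, 2),), ((1, 5), (1, 7)), ((3, 3), (5, 1))],
}


def ld_d_max(q_a: float, q_b: float) -> float:
    """Upper bound on the LD coefficient for minor-allele frequencies q_a, q_b."""
    return min(q_a * (1.0 - q_b), (1.0 - q_a) * q_b)


@dataclass(frozen=True)
class LDConfig:
    """Configuration of one simulated pathway genotype matrix.

    ``D`` is either a fixed LD coefficient applied to every adjacent
    within-gene pair, or the string ``"uniform"``, which draws an independent
    D ~ Uniform(0, D_max) per adjacent pair per simulated matrix.
    """

    n_subjects: int
    gene_sizes: Tuple[int, ...] = DEFAULT_GENE_SIZES
    maf: float = 0.3
    D: Union[float, str] = 0.0
    ploidy: str = "haploid"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.gene_sizes or any(s < 1 for s in self.gene_sizes):
            raise ValueError("gene sizes must be positive integers")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError("ploidy must be 'haploid' or 'diploid'")
        if isinstance(self.D, str):
            if self.D != "uniform":
                raise ValueError("D must be a number or 'uniform'")
        else:
            dmax = self.d_max
            if not -dmax <= self.D <= dmax:
                raise ValueError(
                    f"D = {self.D} outside the admissible range [-{dmax:.4g}, {dmax:.4g}] "
                    f"for maf = {self.maf}"
                )

    @property
    def d_max(self) -> float:
        return ld_d_max(self.maf, self.maf)

    @property
    def n_variants(self) -> int:
        return int(sum(self.gene_sizes))


@dataclass(frozen=True)
class DiseaseModel:
    """A logistic phenotype model: a named case, shared effect size, and terms.

    ``terms`` holds flat variant-column indices; each inner tuple is one
    regression term, products taken over its members.
    """

    case: str
    beta: float
    terms: Tuple[Tuple[int, ...], ...]


def _flat_index(gene: int, locus: int, gene_sizes: Sequence[int]) -> int:
    if not 1 <= gene <= len(gene_sizes):
        raise ValueError(f"gene index {gene} outside the pathway")
    if not 1 <= locus <= gene_sizes[gene - 1]:
        raise ValueError(f"locus {locus} outside gene {gene} (size {gene_sizes[gene - 1]})")
    return int(sum(gene_sizes[: gene - 1]) + locus - 1)


def disease_model(
    case: str, beta: float, gene_sizes: Sequence[int] = DEFAULT_GENE_SIZES
) -> DiseaseModel:
    """Build one of the six canonical disease models for a given pathway layout."""
    if case not in DISEASE_CASES:
        raise ValueError(f"unknown disease case {case!r}; choose from {sorted(DISEASE_CASES)}")
    terms = tuple(
        tuple(_flat_index(g, l, gene_sizes) for g, l in term) for term in DISEASE_CASES[case]
    )
    return DiseaseModel(case=case, beta=float(beta), terms=terms)


def variant_gene_sizes(gene_sizes: Sequence[int]) -> np.ndarray:
    """Per-variant gene size vector: each variant carries its own gene's size."""
    return np.repeat(np.asarray(gene_sizes, dtype=int), gene_sizes)


def _simulate_haplotypes(cfg: LDConfig, rng: np.random.Generator) -> np.ndarray:
    """One 0/1 haplotype matrix (subjects x variants) under the LD chain."""
    q = cfg.maf
    n = cfg.n_subjects
    cols: List[np.ndarray] = []
    for size in cfg.gene_sizes:
        prev = (rng.random(n) < q).astype(np.int8)
        cols.append(prev)
        for _ in range(1, size):
            if cfg.D == "uniform":
                d = rng.uniform(0.0, cfg.d_max)
            else:
                d = float(cfg.D)
            p_a_given_b = (q * q + d) / q
            p_a_given_bb = (q * (1.0 - q) - d) / (1.0 - q)
            prob = np.where(prev == 1, p_a_given_b, p_a_given_bb)
            cur = (rng.random(n) < prob).astype(np.int8)
            cols.append(cur)
            prev = cur
    return np.column_stack(cols)


def simulate_genotypes(cfg: LDConfig, seed=None) -> np.ndarray:
    """Simulate a subjects x variants genotype matrix.

    Haploid mode codes minor-allele presence 0/1; diploid mode sums two
    independent haplotypes (0/1/2).  ``seed`` may be an int, a SeedSequence
    or a Generator.
    """
    rng = np.random.default_rng(seed)
    g = _simulate_haplotypes(cfg, rng)
    if cfg.ploidy == "diploid":
        g = g + _simulate_haplotypes(cfg, rng)
    return g.astype(np.int8)


def simulate_phenotype(genotypes: np.ndarray, model: DiseaseModel, seed=None) -> np.ndarray:
    """Draw binary phenotypes from the logistic model (no intercept).

    With beta = 0 or all-zero genotypes the linear predictor is 0 and
    prevalence is exactly 0.5.
    """
    rng = np.random.default_rng(seed)
    n, p = genotypes.shape
    eta = np.zeros(n)
    for term in model.terms:
        if any(idx >= p for idx in term):
            raise ValueError(f"term {term} refers to a variant outside the matrix ({p} columns)")
        prod = np.ones(n)
        for idx in term:
            prod = prod * genotypes[:, idx]
        eta += model.beta * prod
    return (rng.random(n) < expit(eta)).astype(np.int8)


def trend_pvalues(genotypes: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Two-sided score (trend) test p-value per variant column.

    The score statistic for a single covariate in a logistic model is
    U^2 / V with U = sum x_i (y_i - ybar) and V = ybar (1 - ybar) S_xx,
    referred to chi-square(1).  Constant genotype columns get p = 1.
    """
    y = np.asarray(phenotype, dtype=float)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("phenotype must contain both classes")
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    xbar = g.mean(axis=0)
    sxx = (g * g).sum(axis=0) - n * xbar**2
    u = g.T @ (y - ybar)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = u**2 / (ybar * (1.0 - ybar) * sxx)
    pv = stats.chi2.sf(stat, 1)
    pv[sxx <= 0] = 1.0  # degenerate (constant) variant
    return pv


def _logistic_wald_pvalue(x: np.ndarray, y: np.ndarray, max_iter: int = 50) -> float:
    """Wald p-value for the slope of a one-variant logistic regression (IRLS).

    Returns NaN when the fit diverges (quasi-complete separation), where the
    Wald statistic collapses towards zero (Hauck-Donner effect) and is
    meaningless; callers should fall back to the score test.
    """
    n = x.shape[0]
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        wgt = mu * (1.0 - mu)
        if wgt.max() < 1e-10 or np.abs(beta).max() > 15:  # separation
            return float("nan")
        info = (X.T * wgt) @ X
        try:
            step = np.linalg.solve(info, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return float("nan")
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    mu = expit(X @ beta)
    wgt = mu * (1.0 - mu)
    info = (X.T * wgt) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    se = np.sqrt(max(cov[1, 1], 0.0))
    if se == 0 or not np.isfinite(se):
        return float("nan")
    z = beta[1] / se
    return float(2.0 * stats.norm.sf(abs(z)))


def per_variant_test(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    method: str = "trend",
    ids: Optional[Sequence[str]] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> PValueVector:
    """One two-sided association p-value per variant.

    ``trend`` uses the closed-form score test; ``logistic`` fits a
    single-variant logistic regression per column and reports the Wald test
    (falling back to the score test for a column where the fit degenerates).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.mean() in (0.0, 1.0):
        raise ValueError("phenotype must contain both classes")
    if method == "trend":
        pv = trend_pvalues(genotypes, phenotype)
    elif method == "logistic":
        g = np.asarray(genotypes, dtype=float)
        trend = trend_pvalues(genotypes, phenotype)
        pv = np.empty(g.shape[1])
        for j in range(g.shape[1]):
            if np.ptp(g[:, j]) == 0:
                pv[j] = 1.0
                continue
            pj = _logistic_wald_pvalue(g[:, j], y)
            pv[j] = pj if np.isfinite(pj) and 0.0 < pj <= 1.0 else trend[j]
    else:
        raise ValueError(f"unknown test method {method!r}")
    pv = np.clip(pv, 1e-300, 1.0)  # guard against exact zeros from extreme statistics
    return PValueVector.from_arrays(pv, ids=ids, gene_ids=gene_ids)
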