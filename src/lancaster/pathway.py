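"""Pathway-mode analysis: weighted Lancaster combination per gene set.

Given a table of per-test p-values (tests mapped to genes) and a collection
of gene sets, each set's member p-values are combined with the weighted
Lancaster statistic.  The per-test weight derives from its gene's size
within the table — ``n_i`` is the number of tests (probes/SNPs) mapping to
gene ``i`` — which removes the bias by which large, heavily probed genes
dominate an unweighted combination.  Set-level p-values are then adjusted
across sets by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Optional

import numpy as np
import pandas as pd

from .approx import METHODS, combine_pvalues
from .core import PValueVector, weights_from_gene_sizes
from .io import GeneSetCollection, bh_adjust
from .perm_cov import CovarianceEstimate

__all__ = ["run_pathway_analysis"]

logger = logging.getLogger(__name__)


def run_pathway_analysis(
    pvals: PValueVector,
    sets: GeneSetCollection,
    weight_scheme: str = "inv",
    rho: Optional[CovarianceEstimate] = None,
    primary_method: str = "TA",
) -> pd.DataFrame:
    """Combine per-test p-values within each gene set and BH-adjust across sets.

    Parameters
    ----------
    pvals
        Per-test p-values carrying gene ids.
    sets
        Gene sets; sets with no member gene present in the table are skipped
        with a warning.
    weight_scheme
        Weighting by gene size (tests per gene): ``inv`` (2/n_i), ``inv_sqrt``
        (2/sqrt(n_i)) or ``flat`` (plain Fisher, w = 2).
    rho
        Optional transformed-scale covariance for *all* tests in the table
        (rows/columns in table order); the member submatrix is used per set.
        ``None`` assumes independence.
    primary_method
        The tail approximation whose set-level p-value is BH-adjusted into
        the ``p_adjusted`` column.

    Returns a data frame with one row per analysed set, sorted by adjusted
    p-value.
    """
    if pvals.gene_ids is None:
        raise ValueError("the p-value table must carry gene ids for pathway analysis")
    if primary_method not in METHODS:
        raise ValueError(f"unknown method {primary_method!r}")
    gene_ids = np.asarray(pvals.gene_ids, dtype=object)
    tests_per_gene = Counter(gene_ids.tolist())
    rho_full = None if rho is None else np.asarray(getattr(rho, "rho", rho), dtype=float)
    if rho_full is not None and rho_full.shape != (len(pvals), len(pvals)):
        raise ValueError("rho dimension must match the number of tests in the table")

    rows = []
    for set_id, (desc, members) in sets.sets.items():
        mask = np.isin(gene_ids, list(members))
        if not mask.any():
            logger.warning("gene set %s has no member gene in the p-value table; skipped", set_id)
            continue
        idx = np.flatnonzero(mask)
        member_genes = gene_ids[idx]
        sizes = np.array([tests_per_gene[g] for g in member_genes])
        w = weights_from_gene_sizes(sizes, scheme=weight_scheme)
        sub_p = PValueVector.from_arrays(
            pvals.values[idx], ids=[pvals.ids[i] for i in idx], gene_ids=member_genes.tolist()
        )
        sub_rho = None if rho_full is None else rho_full[np.ix_(idx, idx)]
        res = combine_pvalues(sub_p, w, sub_rho)
        row = {
            "set_id": set_id,
            "description": desc,
            "n_genes": int(len(set(member_genes.tolist()))),
            "n_tests": int(idx.size),
            "T": res.T,
            "df": res.moments.mean,
        }
        for name in METHODS:
            row[f"p_{name}"] = res.pvalues[name]
        rows.append(row)
    if not rows:
        raise ValueError("no gene set overlaps the p-value table")
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df[f"p_{primary_method}"].to_numpy())
    return df.sort_values("p_adjusted", kind="mergesort").reset_index(drop=True)
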