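"""Readers and writers for p-value tables, gene sets (GMT) and matrices.

Formats are deliberately plain text: p-value tables are TSV with columns
``test_id``, ``gene_id``, ``p``; gene sets use the community-standard GMT
layout (set id, description, member genes, tab-separated); genotype and
covariance matrices are TSV with a header row of column identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .core import PValueVector

__all__ = [
    "GeneSetCollection",
    "read_pvalue_table",
    "read_gmt",
    "bh_adjust",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_phenotype_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: set id -> (description, tuple of unique member genes)."""

    sets: Dict[str, Tuple[str, Tuple[str, ...]]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_pvalue_table(path) -> PValueVector:
    """Read a TSV of per-test p-values with columns test_id, gene_id, p."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    required = {"test_id", "gene_id", "p"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    p = pd.to_numeric(df["p"], errors="coerce")
    bad = df.index[p.isna() | (p <= 0) | (p > 1)]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: p-value outside (0, 1] or malformed at line {bad[0] + 2}")
    if df["test_id"].duplicated().any():
        dup = df.loc[df["test_id"].duplicated(), "test_id"].iloc[0]
        raise ValueError(f"{path}: duplicated test_id {dup!r}")
    return PValueVector.from_arrays(
        p.to_numpy(), ids=df["test_id"].tolist(), gene_ids=df["gene_id"].tolist()
    )


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (set id TAB description TAB member...)."""
    sets: Dict[str, Tuple[str, Tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            set_id, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m.strip()))
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set id {set_id!r}")
            sets[set_id] = (desc, members)
    if not sets:
        logger.warning("%s: empty gene-set collection", path)
    return GeneSetCollection(sets=sets, source=str(path))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot adjust an empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def read_matrix_tsv(path) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """Read a numeric matrix with a header row of column ids (e.g. genotypes)."""
    df = pd.read_csv(path, sep="\t")
    mat = df.to_numpy(dtype=float)
    if np.any(np.isnan(mat)):
        raise ValueError(f"{path}: missing values are not supported")
    return mat, tuple(str(c) for c in df.columns)


def write_matrix_tsv(path, matrix: np.ndarray, columns) -> None:
    pd.DataFrame(np.asarray(matrix), columns=list(columns)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_phenotype_tsv(path) -> np.ndarray:
    """Read a single-column 0/1 phenotype vector (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None)
    col = df.iloc[:, 0]
    if isinstance(col.iloc[0], str) and not col.iloc[0].lstrip("-").isdigit():
        col = col.iloc[1:]
    y = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"{path}: phenotype must be coded 0/1")
    return y.astype(np.int8)
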