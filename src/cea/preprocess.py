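"""Derive active gene lists from two-group expression matrices.

The recipe: per-gene two-sample t-test between the disease and control
groups, sort genes by ascending p-value, take the top ``top_n`` (default
100) as differentially expressed, then keep those with at least one
annotation — that filtered list is the active gene set ``U_G``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import AnnotationDB
from .stats import ActiveGeneSet

logger = logging.getLogger(__name__)

__all__ = ["load_expression", "load_groups", "gene_pvalues", "derive_active_genes"]


def load_expression(path: str | Path) -> pd.DataFrame:
    """Genes-by-samples TSV with a header row; rows with missing values dropped."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    before = len(df)
    df = df.dropna(axis=0)
    if len(df) < before:
        logger.warning("dropped %d genes with missing values", before - len(df))
    return df


def load_groups(path: str | Path) -> pd.Series:
    """Two-column TSV (sample id, group label) -> sample->label Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#")
    return df.set_index("sample")["group"]


def gene_pvalues(expr: pd.DataFrame, groups: pd.Series, test: str = "welch") -> pd.Series:
    """Two-sided two-sample t-test p-value per gene.

    ``test='welch'`` uses the unequal-variance statistic, ``'student'`` the
    pooled-variance one.  Genes whose statistic is undefined (e.g. constant
    expression in both groups) get p = 1 so they sort last.
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    labels = groups.reindex(expr.columns)
    if labels.isna().any():
        missing = list(expr.columns[labels.isna()])[:3]
        raise ValueError(f"samples without a group label, e.g. {missing}")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {levels}")
    a = expr.loc[:, labels == levels[0]].to_numpy()
    b = expr.loc[:, labels == levels[1]].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.Series(p, index=expr.index, name="p")


def derive_active_genes(
    expr: pd.DataFrame,
    groups: pd.Series,
    db: AnnotationDB,
    top_n: int = 100,
    test: str = "welch",
) -> ActiveGeneSet:
    """Active gene set: top differentially expressed genes with >=1 annotation.

    Ties at the ``top_n`` boundary are resolved by a stable sort on
    ``(p, gene id)`` so the cut is reproducible.  The annotation filter is
    applied *after* the top-``top_n`` cut, so ``|U_G| <= top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pvals = gene_pvalues(expr, groups, test=test)
    order = pvals.to_frame().assign(gene=pvals.index).sort_values(["p", "gene"], kind="mergesort")
    if top_n > len(order):
        logger.warning("top_n=%d exceeds the %d available genes; using all", top_n, len(order))
        top_n = len(order)
    top = list(order.index[:top_n])
    annotated = [g for g in top if g in db.coverage_index]
    if not annotated:
        raise ValueError("no annotated gene among the top differentially expressed genes")
    if len(annotated) < len(top):
        logger.info("annotation filter: %d of %d top genes kept", len(annotated), len(top))
    return ActiveGeneSet.from_genes(annotated, db)
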