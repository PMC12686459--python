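"""One-vs-rest differential expression with the pipeline's filtering and
ranking rules.

The test is a two-sided Wilcoxon rank-sum (normal approximation with tie
correction) per gene on log-normalized values. Candidate markers are then
filtered — ribosomal/mitochondrial symbols excluded, genes detected in fewer
than 10% of the cluster's cells dropped — and ranked by

    ranking = (-ln adjusted_p) * log2_fold_change,

with Benjamini-Hochberg adjusted p-values floored at 1e-300 to keep the
ranking finite. Signature gene sets are the top-n genes of the ranked table.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io import densify

__all__ = ["wilcoxon_markers", "filter_markers", "rank_markers", "top_n"]

ADJ_P_FLOOR = 1e-300
DEFAULT_EXCLUDE_PREFIXES = ("RPS", "RPL", "MRPS", "MRPL", "MT-")


def _tie_term(column: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of one gene's values."""
    _, counts = np.unique(column, return_counts=True)
    ties = counts[counts > 1]
    return float((ties**3 - ties).sum())


def wilcoxon_markers(
    norm_adata: ad.AnnData, labels: Sequence[str] | pd.Series, group: str
) -> pd.DataFrame:
    """Rank-sum test of ``group`` cells against all other cells, per gene.

    Returns a table with columns gene, group, log2_fc, pct_in, pct_out,
    p_value, adj_p (and ranking = NaN until :func:`rank_markers` is applied).
    The fold change is ``log2((expm1(mean_in)+eps)/(expm1(mean_out)+eps))``
    with eps = 1e-9, means taken on the log-normalized scale.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != norm_adata.n_obs:
        raise ValueError("labels length must match number of cells")
    in_group = labels == group
    if not in_group.any():
        raise ValueError(f"group {group!r} absent from labels")
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 cells inside and outside the group")
    n = n1 + n2

    X = densify(norm_adata.X)
    ranks = rankdata(X, axis=0)
    rank_sum = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    tie_terms = np.array([_tie_term(X[:, j]) for j in range(X.shape[1])])
    var = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (rank_sum - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = np.where(var > 0, 2 * norm.sf(np.abs(z)), 1.0)

    eps = 1e-9
    mean_in = X[in_group].mean(axis=0)
    mean_out = X[~in_group].mean(axis=0)
    log2_fc = np.log2((np.expm1(mean_in) + eps) / (np.expm1(mean_out) + eps))
    log2_fc = np.where(var > 0, log2_fc, 0.0)

    adj_p = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": list(norm_adata.var_names),
            "group": group,
            "log2_fc": log2_fc,
            "pct_in": (X[in_group] > 0).mean(axis=0),
            "pct_out": (X[~in_group] > 0).mean(axis=0),
            "p_value": p,
            "adj_p": adj_p,
            "ranking": np.nan,
        }
    )
    return table


def filter_markers(
    table: pd.DataFrame,
    min_pct_in: float = 0.10,
    exclude_prefixes: Sequence[str] = DEFAULT_EXCLUDE_PREFIXES,
) -> pd.DataFrame:
    """Drop ribosomal/mitochondrial symbols and genes detected below
    ``min_pct_in`` within the cluster (strictly-below rule)."""
    excluded_symbol = table["gene"].str.startswith(tuple(exclude_prefixes))
    keep = (table["pct_in"] >= min_pct_in) & ~excluded_symbol
    out = table[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("all candidate markers removed by the filters")
    return out


def rank_markers(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the ranking score and sort the table by it, descending.

    Ties in ranking are broken by smaller adjusted p, then gene symbol.
    """
    out = table.copy()
    out["ranking"] = -np.log(np.maximum(out["adj_p"].values, ADJ_P_FLOOR)) * out[
        "log2_fc"
    ].values
    out = out.sort_values(
        ["ranking", "adj_p", "gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out


def top_n(table: pd.DataFrame, n: int) -> list[str]:
    """First ``n`` genes of the ranked table (a signature gene set)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if table["ranking"].isna().any():
        table = rank_markers(table)
    if len(table) < n:
        warnings.warn(f"table has only {len(table)} genes; returning all of them")
    return list(table["gene"].head(n))
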