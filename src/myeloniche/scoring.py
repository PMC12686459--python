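"""Gene-set scoring of cells and spots.

Two scoring methods are provided:

* **rank-AUC** — per cell, all genes are ranked by expression (descending,
  ties broken by a seeded random permutation), and the score is the
  normalized area under the gene set's recovery curve over the top
  ``top_frac`` of the ranking. The score lies in [0, 1], is 1 when the whole
  set occupies the top ranks, 0 when no member appears in the top fraction,
  and is invariant to any monotone transform of a cell's expression values.
* **bin-matched control** — the mean expression of the gene set minus the
  mean of an expression-matched control pool sampled per set gene from its
  average-expression bin.

The maturation score orders cells along an early->late program by
subtracting the early set's rank-AUC from the late set's.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .io import densify

__all__ = [
    "rank_auc_score",
    "bin_control_score",
    "maturation_score",
    "subtype_signature_scores",
]


def _resolve_genes(adata: ad.AnnData, genes: Sequence[str]) -> np.ndarray:
    names = pd.Index(adata.var_names)
    present = [g for g in genes if g in names]
    missing = [g for g in genes if g not in names]
    if missing:
        warnings.warn(f"{len(missing)} gene-set genes absent from the matrix; dropped")
    if not present:
        raise ValueError("no gene-set genes present in the matrix")
    return names.get_indexer(present)


def rank_auc_score(
    norm_adata: ad.AnnData,
    genes: Sequence[str],
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Recovery-curve area of a gene set within each cell's expression ranking.

    With G genes and L = ceil(top_frac * G), the recovery curve at rank r
    (r = 1..L) is the number of set members among the cell's top r genes; the
    score is the curve's area (rectangle rule at integer ranks) divided by
    the maximal achievable area, in which all members occupy the top ranks.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    member_idx = _resolve_genes(norm_adata, genes)
    X = densify(norm_adata.X)
    n_cells, G = X.shape
    L = math.ceil(top_frac * G)
    member = np.zeros(G, dtype=bool)
    member[member_idx] = True
    M = int(member.sum())

    # maximal area: members at ranks 1..M contribute min(r, M) at each rank r
    m_eff = min(M, L)
    max_area = m_eff * (m_eff + 1) / 2 + (L - m_eff) * m_eff

    tiebreak = np.random.default_rng(seed).permutation(G)
    scores = np.empty(n_cells)
    for c in range(n_cells):
        order = np.lexsort((tiebreak, -X[c]))  # descending expression, seeded ties
        hits = member[order[:L]]
        scores[c] = np.cumsum(hits).sum() / max_area
    return pd.Series(scores, index=norm_adata.obs_names, name="rank_auc")


def bin_control_score(
    norm_adata: ad.AnnData,
    genes: Sequence[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Mean set expression minus the mean of a bin-matched control pool.

    Genes are binned into ``n_bins`` by average expression; each set gene
    draws ``ctrl_size`` control genes from its own bin (without replacement
    where possible, with replacement and a warning otherwise).
    """
    member_idx = _resolve_genes(norm_adata, genes)
    X = densify(norm_adata.X)
    G = X.shape[1]
    rng = np.random.default_rng(seed)

    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(G, dtype=int)
    bin_of[order] = np.floor(np.arange(G) / G * n_bins).astype(int)

    member = np.zeros(G, dtype=bool)
    member[member_idx] = True
    control_idx: list[np.ndarray] = []
    for g in member_idx:
        pool = np.flatnonzero((bin_of == bin_of[g]) & ~member)
        if pool.size == 0:
            warnings.warn("gene set covers an entire expression bin; sampling controls with replacement from the bin")
            pool = np.flatnonzero(bin_of == bin_of[g])
            control_idx.append(rng.choice(pool, size=ctrl_size, replace=True))
        elif pool.size < ctrl_size:
            control_idx.append(pool)
        else:
            control_idx.append(rng.choice(pool, size=ctrl_size, replace=False))
    controls = np.unique(np.concatenate(control_idx))

    score = X[:, member_idx].mean(axis=1) - X[:, controls].mean(axis=1)
    return pd.Series(score, index=norm_adata.obs_names, name="bin_control")


def maturation_score(
    norm_adata: ad.AnnData,
    early: Sequence[str],
    late: Sequence[str],
    top_frac: float = 0.05,
    seed: int = 0,
    group_labels: Sequence[str] | None = None,
) -> pd.Series | tuple[pd.Series, pd.Series, float]:
    """Late-program rank-AUC minus early-program rank-AUC, per cell.

    When ``group_labels`` is given, additionally returns the per-group mean
    score and the cross-group mean (the dashed-line reference level).
    """
    late_s = rank_auc_score(norm_adata, late, top_frac=top_frac, seed=seed)
    early_s = rank_auc_score(norm_adata, early, top_frac=top_frac, seed=seed)
    score = (late_s - early_s).rename("maturation")
    if group_labels is None:
        return score
    groups = pd.Series(np.asarray(group_labels), index=score.index)
    group_means = score.groupby(groups).mean()
    return score, group_means, float(group_means.mean())


def subtype_signature_scores(
    norm_adata: ad.AnnData,
    signatures: Mapping[str, Sequence[str]],
    method: str = "rank_auc",
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Score every signature on every cell; returns cells x signatures."""
    if not signatures:
        raise ValueError("signatures must be nonempty")
    scorers = {"rank_auc": rank_auc_score, "bin_control": bin_control_score}
    if method not in scorers:
        raise ValueError(f"unknown scoring method {method!r}")
    cols = {
        name: scorers[method](norm_adata, genes, seed=seed, **kwargs)
        for name, genes in signatures.items()
    }
    return pd.DataFrame(cols, index=norm_adata.obs_names)
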