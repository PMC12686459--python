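"""Quality-control filters, log-normalization and highly-variable-gene
selection for cell and spot count matrices.

Filter boundaries follow strict inequalities: a cell expressing fewer than
``min_genes_per_cell`` genes or more than ``max_mito_fraction`` mitochondrial
counts is removed, a gene detected in fewer than ``min_cells_per_gene`` cells
is removed, and spots with total counts below ``spot_min_counts`` or above
``spot_max_counts`` are removed — values equal to a threshold are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "filter_cells",
    "filter_genes",
    "filter_spots",
    "lognormalize",
    "select_hvg",
]


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 150
    max_mito_fraction: float = 0.25
    min_cells_per_gene: int = 3
    spot_min_counts: int = 2500
    spot_max_counts: int = 75000
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-")

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if min(self.min_genes_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.spot_min_counts >= self.spot_max_counts:
            raise ValueError("spot_min_counts must be < spot_max_counts")


def _row_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    return sp.csr_matrix(adata.X)


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Remove low-quality cells: too few expressed genes or too mitochondrial."""
    t = thresholds or QCThresholds()
    X = _row_matrix(adata)
    n_genes = X.getnnz(axis=1)
    mito_mask = np.array(
        [any(name.startswith(p) for p in t.mito_prefixes) for name in adata.var_names]
    )
    if not mito_mask.any():
        warnings.warn("no mitochondrial-prefixed genes found; mito filter is vacuous")
        mito_frac = np.zeros(adata.n_obs)
    else:
        totals = np.asarray(X.sum(axis=1)).ravel()
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (n_genes >= t.min_genes_per_cell) & (mito_frac <= t.max_mito_fraction)
    logger.info("filter_cells removed %d of %d cells", int((~keep).sum()), adata.n_obs)
    return adata[keep].copy()


def filter_genes(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Remove genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells."""
    t = thresholds or QCThresholds()
    X = _row_matrix(adata)
    detected = X.getnnz(axis=0)
    keep = detected >= t.min_cells_per_gene
    if not keep.any():
        raise ValueError("all genes removed by the detection filter")
    logger.info("filter_genes removed %d of %d genes", int((~keep).sum()), adata.n_vars)
    return adata[:, keep].copy()


def filter_spots(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Keep spots whose total counts lie in [spot_min_counts, spot_max_counts]."""
    t = thresholds or QCThresholds()
    totals = np.asarray(_row_matrix(adata).sum(axis=1)).ravel()
    keep = (totals >= t.spot_min_counts) & (totals <= t.spot_max_counts)
    if not keep.any():
        raise ValueError("all spots removed by the count filter")
    logger.info("filter_spots removed %d of %d spots", int((~keep).sum()), adata.n_obs)
    return adata[keep].copy()


def lognormalize(adata: ad.AnnData, target_sum: float | str = "median") -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    ``target_sum="median"`` (the default) scales to the median of per-cell
    totals. All-zero cells are left all-zero with a warning.
    """
    totals = np.asarray(_row_matrix(adata).sum(axis=1)).ravel()
    if (totals == 0).all():
        raise ValueError("matrix has no nonzero row")
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} all-zero cells left unnormalized")
    out = adata.copy()
    out.X = sp.csr_matrix(out.X, dtype=np.float64)
    ts = None if target_sum == "median" else float(target_sum)
    sc.pp.normalize_total(out, target_sum=ts)
    sc.pp.log1p(out)
    out.uns["target_sum"] = float(np.median(totals[totals > 0])) if ts is None else ts
    return out


def select_hvg(
    norm: ad.AnnData,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
    n_bins: int = 20,
) -> list[str]:
    """Highly variable genes by binned-dispersion cutoffs.

    Per-gene mean and dispersion (variance/mean) are computed on the
    exponentiated (expm1) values, dispersions are z-scored within mean bins,
    and genes with mean inside (min_mean, max_mean) and normalized dispersion
    above ``min_disp`` are returned.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    work = norm.copy()
    sc.pp.highly_variable_genes(
        work,
        flavor="seurat",
        min_mean=min_mean,
        max_mean=max_mean,
        min_disp=min_disp,
        n_bins=n_bins,
    )
    hvgs = list(work.var_names[work.var["highly_variable"]])
    if not hvgs:
        warnings.warn("no highly variable genes at these cutoffs")
    return hvgs
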