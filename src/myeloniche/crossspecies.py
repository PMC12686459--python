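"""Mapping human subtype signatures onto mouse data and clustering subtypes
across species.

Human marker sets are translated through a mouse-human ortholog table
(many-to-many entries expanded then deduplicated) and scored on mouse cells
with the bin-matched control method. For joint subtype clustering, genes
that are highly variable in both species are kept, subtype-average
expression matrices are concatenated on the shared (human-symbol) gene
axis, each gene column is divided by its median across subtypes (zero-median
genes dropped), log2(x+1) is applied, and both axes are clustered
hierarchically with correlation distance and average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist

from . import markers as _markers
from . import preprocess
from .io import densify
from .scoring import bin_control_score

__all__ = [
    "map_orthologs",
    "ortholog_signature_scores",
    "CrossSpeciesClustering",
    "cross_species_cluster",
    "nearest_neighbors",
]


def map_orthologs(
    genes: Sequence[str], om: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Translate human symbols to mouse symbols through the ortholog table.

    Many-to-many entries are expanded then deduplicated (first occurrence
    kept). Returns (mouse symbols, unmapped human symbols); raises if no
    gene maps.
    """
    if om.empty:
        raise ValueError("ortholog table is empty")
    genes = list(genes)
    hits = om[om["human_symbol"].isin(genes)]
    mapped_humans = set(hits["human_symbol"])
    unmapped = [g for g in genes if g not in mapped_humans]
    mouse = list(dict.fromkeys(hits["mouse_symbol"]))
    if not mouse:
        raise ValueError("no genes could be mapped to mouse symbols")
    return mouse, unmapped


def ortholog_signature_scores(
    mouse_norm: ad.AnnData,
    human_markers: Mapping[str, pd.DataFrame],
    om: pd.DataFrame,
    n: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each human subtype's top-n ortholog signature on mouse cells."""
    cols = {}
    for subtype, table in human_markers.items():
        top = _markers.top_n(table, n)
        try:
            mouse_genes, _ = map_orthologs(top, om)
            cols[subtype] = bin_control_score(mouse_norm, mouse_genes, seed=seed)
        except ValueError:
            warnings.warn(f"subtype {subtype!r} has no mapped signature genes; dropped")
    if not cols:
        raise ValueError("no subtype signature could be mapped and scored")
    return pd.DataFrame(cols, index=mouse_norm.obs_names)


@dataclass
class CrossSpeciesClustering:
    matrix: pd.DataFrame  # subtypes x genes, median-normalized, log2(x+1)
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def _subtype_means(norm_adata: ad.AnnData, labels: Sequence[str]) -> pd.DataFrame:
    labels = pd.Series(np.asarray(labels), index=norm_adata.obs_names)
    X = np.expm1(densify(norm_adata.X))
    rows = {
        subtype: X[(labels == subtype).values].mean(axis=0)
        for subtype in sorted(labels.unique())
    }
    return pd.DataFrame(rows, index=norm_adata.var_names).T


def cross_species_cluster(
    human_norm: ad.AnnData,
    human_labels: Sequence[str],
    mouse_norm: ad.AnnData,
    mouse_labels: Sequence[str],
    om: pd.DataFrame,
    hvg_params: dict | None = None,
    min_shared_genes: int = 10,
) -> CrossSpeciesClustering:
    """Cluster human and mouse subtypes jointly on conserved variable genes.

    Rows of the output matrix are subtypes prefixed ``hs:`` / ``mm:``;
    columns are the conserved genes (human symbols). When several mouse
    genes map to one human symbol, their mouse expression is averaged.
    """
    if pd.Series(np.asarray(human_labels)).nunique() < 2:
        raise ValueError("need at least 2 human subtypes")
    if pd.Series(np.asarray(mouse_labels)).nunique() < 2:
        raise ValueError("need at least 2 mouse subtypes")
    hvg_params = hvg_params or {}
    hvg_h = set(preprocess.select_hvg(human_norm, **hvg_params))
    hvg_m = set(preprocess.select_hvg(mouse_norm, **hvg_params))

    pairs = om[om["human_symbol"].isin(hvg_h) & om["mouse_symbol"].isin(hvg_m)]
    pairs = pairs.drop_duplicates()
    if pairs["human_symbol"].nunique() < min_shared_genes:
        raise ValueError(
            f"fewer than {min_shared_genes} conserved highly variable genes"
        )

    h_means = _subtype_means(human_norm, human_labels)
    m_means = _subtype_means(mouse_norm, mouse_labels)
    human_genes = list(dict.fromkeys(pairs["human_symbol"]))
    h_block = h_means[human_genes]
    # mouse expression on the human-symbol axis, averaging many-to-one targets
    m_cols = {
        hg: m_means[pairs.loc[pairs["human_symbol"] == hg, "mouse_symbol"].unique()].mean(axis=1)
        for hg in human_genes
    }
    m_block = pd.DataFrame(m_cols)[human_genes]

    combined = pd.concat(
        [h_block.rename(index=lambda s: f"hs:{s}"), m_block.rename(index=lambda s: f"mm:{s}")]
    )
    med = combined.median(axis=0)
    combined = combined.loc[:, med > 0].div(med[med > 0], axis=1)
    combined = np.log2(combined + 1.0)
    if combined.shape[1] < min_shared_genes:
        raise ValueError("too few genes remain after median normalization")

    row_link = linkage(pdist(combined.values, metric="correlation"), method="average")
    col_link = linkage(pdist(combined.values.T, metric="correlation"), method="average")
    return CrossSpeciesClustering(matrix=combined, row_linkage=row_link, col_linkage=col_link)


def nearest_neighbors(result: CrossSpeciesClustering) -> pd.Series:
    """Each subtype's nearest other subtype by cophenetic dendrogram distance."""
    coph = squareform_from_linkage(result.row_linkage)
    names = list(result.matrix.index)
    np.fill_diagonal(coph, np.inf)
    nearest = [names[int(np.argmin(coph[i]))] for i in range(len(names))]
    return pd.Series(nearest, index=names, name="nearest")


def squareform_from_linkage(Z: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform

    return squareform(cophenet(Z))
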