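"""Reference-based estimation of cell-subtype proportions.

A subtype reference profile (mean linear-scale normalized expression per
gene) is built from labeled single-cell data, and each bulk sample or
spatial spot is decomposed against it by nonnegative least squares: genes
are intersected, the sample and each reference profile are scaled to unit
totals for conditioning, NNLS is solved, and the coefficients are unscaled,
clipped at zero and normalized to sum one. The per-sample residual is the
relative L2 misfit. Proportions are scale invariant in the sample and
equivariant under permutation of reference rows.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.optimize

from .io import densify

__all__ = ["build_reference", "decompose", "decompose_matrix"]


def build_reference(
    norm_adata: ad.AnnData,
    labels: Sequence[str] | pd.Series,
    gene_subset: Sequence[str] | None = None,
    prefilter_min_cells: int | None = None,
) -> pd.DataFrame:
    """Per-subtype mean expm1 of log-normalized expression, subtypes x genes.

    ``gene_subset`` (typically the union of top marker sets) restricts the
    reference to informative genes, which reduces collinearity between
    subtype profiles. ``prefilter_min_cells`` optionally drops genes
    detected in fewer than that many cells before profiles are averaged.
    Cell counts per subtype are stored in ``attrs``.
    """
    labels = pd.Series(np.asarray(labels), index=norm_adata.obs_names)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"subtypes with fewer than 2 cells: {sorted(small.index)}")
    if prefilter_min_cells is not None:
        detected = np.asarray((densify(norm_adata.X) > 0).sum(axis=0)).ravel()
        norm_adata = norm_adata[:, detected >= prefilter_min_cells]
        if norm_adata.n_vars == 0:
            raise ValueError("prefilter removed every gene")
    X = np.expm1(densify(norm_adata.X))
    profiles = {}
    for subtype in counts.index:
        profiles[subtype] = X[(labels == subtype).values].mean(axis=0)
    ref = pd.DataFrame(profiles, index=norm_adata.var_names).T.sort_index()
    if gene_subset is not None:
        present = [g for g in gene_subset if g in ref.columns]
        if not present:
            raise ValueError("gene_subset shares no genes with the matrix")
        ref = ref[present]
    if (ref.sum(axis=1) == 0).any():
        raise ValueError("reference contains an all-zero subtype profile")
    ref.attrs["n_cells"] = counts.to_dict()
    return ref


def decompose(
    sample: pd.Series | np.ndarray,
    ref: pd.DataFrame,
    gene_names: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Estimate subtype proportions of one expression vector by NNLS.

    ``sample`` may be a named Series or a plain vector accompanied by
    ``gene_names``. Returns (proportions summing to 1, relative L2 residual).
    """
    if isinstance(sample, pd.Series):
        s = sample
    else:
        if gene_names is None:
            raise ValueError("plain vectors need gene_names")
        s = pd.Series(np.asarray(sample, dtype=float), index=list(gene_names))
    shared = ref.columns.intersection(s.index)
    K = ref.shape[0]
    if len(shared) < K:
        raise ValueError(f"need at least {K} shared genes, found {len(shared)}")
    b = s.loc[shared].to_numpy(dtype=float)
    if b.sum() <= 0:
        raise ValueError("sample is all zero on the shared genes")
    A = ref[shared].to_numpy(dtype=float).T  # genes x subtypes

    col_scale = A.sum(axis=0)
    if (col_scale == 0).any():
        raise ValueError("reference profile all zero on the shared genes")
    if np.linalg.matrix_rank(A) < K:
        warnings.warn("rank-deficient reference; NNLS solution may not be unique")
    A_s = A / col_scale
    b_s = b / b.sum()
    w, _ = scipy.optimize.nnls(A_s, b_s)
    resid = float(np.linalg.norm(A_s @ w - b_s) / np.linalg.norm(b_s))
    w = np.clip(w / col_scale, 0.0, None)  # back to the reference's scale
    if w.sum() == 0:
        raise ValueError("NNLS returned an all-zero solution")
    props = pd.Series(w / w.sum(), index=ref.index, name="proportion")
    return props, resid


def decompose_matrix(samples: ad.AnnData, ref: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`decompose`; failed rows are excluded with a warning.

    Returns samples x subtypes proportions with the per-sample residual in
    ``attrs["residual"]``.
    """
    X = densify(samples.X)
    genes = list(samples.var_names)
    rows, resids, kept, failed = [], [], [], []
    for i, name in enumerate(samples.obs_names):
        try:
            props, resid = decompose(X[i], ref, gene_names=genes)
        except ValueError as exc:
            failed.append((name, str(exc)))
            continue
        rows.append(props)
        resids.append(resid)
        kept.append(name)
    if failed:
        warnings.warn(f"{len(failed)} samples failed decomposition and were excluded")
    if not rows:
        raise ValueError("no sample could be decomposed")
    out = pd.DataFrame(rows, index=kept)
    out.attrs["residual"] = pd.Series(resids, index=kept, name="residual")
    out.attrs["failed"] = failed
    return out
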