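"""Readers and writers for the plain-text formats used across the pipeline.

Count matrices travel as CellRanger-style Matrix-Market triplets
(``matrix.mtx`` with genes as rows, plus ``features.tsv`` / ``barcodes.tsv``
sidecars), gene sets as GMT, and everything tabular as CSV/TSV.
"""

from __future__ import annotations

import os
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_mtx_dir",
    "write_mtx_dir",
    "read_gmt",
    "write_gmt",
    "read_ortholog_table",
    "write_ortholog_table",
]


def write_mtx_dir(adata: ad.AnnData, path: str) -> None:
    """Write ``adata`` (cells/spots x genes) as a CellRanger-dialect triplet.

    The .mtx stores genes as rows, so the matrix is transposed on disk.
    """
    os.makedirs(path, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), X.T.tocoo())
    feats = pd.DataFrame(
        {"id": adata.var_names, "name": adata.var_names, "type": "Gene Expression"}
    )
    feats.to_csv(os.path.join(path, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_mtx_dir(path: str) -> ad.AnnData:
    """Read a CellRanger-dialect Matrix-Market directory into AnnData."""
    X = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
    feats = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)
    adata = ad.AnnData(X=sp.csr_matrix(X.T))
    adata.var_names = feats.iloc[:, 0].astype(str).values
    adata.obs_names = barcodes.iloc[:, 0].astype(str).values
    return adata


def read_gmt(path: str) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_ortholog_table(path: str) -> pd.DataFrame:
    """Read a two-column (mouse_symbol, human_symbol) TSV."""
    om = pd.read_csv(path, sep="\t")
    required = {"mouse_symbol", "human_symbol"}
    if not required.issubset(om.columns):
        raise ValueError(f"ortholog table must have columns {sorted(required)}")
    return om[["mouse_symbol", "human_symbol"]]


def write_ortholog_table(om: pd.DataFrame, path: str) -> None:
    om[["mouse_symbol", "human_symbol"]].to_csv(path, sep="\t", index=False)


def densify(X) -> np.ndarray:
    """Return a 2-D float ndarray view of a (possibly sparse) matrix."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)
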