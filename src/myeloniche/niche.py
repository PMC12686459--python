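"""Spatial analyses on the spot-level proportion matrix.

Covers subtype colocalization (Pearson across spots), abundance-signature
correlation under a dual-significance rule (both the spot-level pathway p
and the correlation p must be < 0.05), composition-based region clustering
(k-means on proportion rows), relative niche calling (clusters whose mean
abundance of every target subtype and signature is at least ``z_min``
standard deviations above the across-cluster mean), and a permutation-tested
ligand-receptor co-expression score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import densify

__all__ = [
    "RegionClustering",
    "colocalization_matrix",
    "abundance_signature_correlation",
    "cluster_spots",
    "call_niche",
    "lr_score",
]

_Z_GUARD = 1e-9  # floating guard on the z >= z_min comparison


@dataclass
class RegionClustering:
    labels: pd.Series  # per-spot cluster id in [0, k)
    k: int
    cluster_composition: pd.DataFrame  # cluster x subtype mean proportions


def colocalization_matrix(P: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every subtype pair across spots.

    Returns (r_matrix, p_matrix); constant columns yield NaN with a warning.
    """
    if len(P) < 3:
        raise ValueError("need at least 3 spots")
    cols = list(P.columns)
    constant = [c for c in cols if P[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant subtype columns, correlation undefined: {constant}")
    K = len(cols)
    r = np.full((K, K), np.nan)
    p = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(i, K):
            if cols[i] in constant or cols[j] in constant:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(P[cols[i]], P[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def abundance_signature_correlation(
    P: pd.DataFrame,
    spot_scores: pd.DataFrame,
    spot_p: pd.DataFrame | None = None,
    alpha: float = 0.05,
    restrict_spots: bool = True,
) -> pd.DataFrame:
    """Correlate subtype abundance with signature scores across spots.

    A (subtype, signature) pair is significant only if the correlation p is
    below ``alpha`` AND, when per-spot signature p-values are supplied, the
    spot-level p is also below ``alpha``. The default reading restricts the
    correlation to the spots where the signature itself is significant
    (``restrict_spots=True``); ``restrict_spots=False`` instead computes the
    correlation over all spots and requires every spot's signature p < alpha.
    """
    if not P.index.equals(spot_scores.index):
        raise ValueError("P and spot_scores must be aligned on the same spots")
    records = []
    for subtype in P.columns:
        for signature in spot_scores.columns:
            x = P[subtype]
            y = spot_scores[signature]
            if spot_p is not None:
                sig_spots = spot_p[signature] < alpha
                if restrict_spots:
                    x, y = x[sig_spots], y[sig_spots]
                gate_ok = bool(sig_spots.all()) if not restrict_spots else True
            else:
                gate_ok = True
            if len(x) < 3 or x.nunique() <= 1 or y.nunique() <= 1:
                records.append((subtype, signature, np.nan, np.nan, False, True))
                continue
            res = stats.pearsonr(x, y)
            significant = gate_ok and res.pvalue < alpha
            records.append(
                (subtype, signature, res.statistic, res.pvalue, significant, False)
            )
    return pd.DataFrame(
        records, columns=["subtype", "signature", "r", "p", "significant", "insufficient"]
    )


def cluster_spots(P: pd.DataFrame, k: int, seed: int = 0) -> RegionClustering:
    """k-means (10 restarts, seeded) on the proportion rows."""
    if not 1 <= k <= len(P):
        raise ValueError("k must be in [1, n_spots]")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = pd.Series(km.fit_predict(P.values), index=P.index, name="region_cluster")
    comp = P.groupby(labels).mean()
    comp.index.name = "cluster"
    return RegionClustering(labels=labels, k=k, cluster_composition=comp)


def call_niche(
    rc: RegionClustering,
    P: pd.DataFrame,
    spot_scores: pd.DataFrame,
    target_subtypes: Sequence[str],
    target_signatures: Sequence[str],
    z_min: float = 1.0,
) -> list[int]:
    """Clusters whose mean of every target abundance/signature is high.

    Each cluster's mean of each target is z-scored across clusters; clusters
    where all targets reach ``z_min`` are returned.
    """
    if rc.k < 2:
        raise ValueError("need at least 2 clusters to z-score across clusters")
    missing = set(target_subtypes) - set(P.columns)
    if missing:
        raise ValueError(f"target subtypes absent from P: {sorted(missing)}")
    missing = set(target_signatures) - set(spot_scores.columns)
    if missing:
        raise ValueError(f"target signatures absent from scores: {sorted(missing)}")
    features = pd.concat(
        [P[list(target_subtypes)], spot_scores[list(target_signatures)]], axis=1
    )
    cluster_means = features.groupby(rc.labels).mean()
    z = (cluster_means - cluster_means.mean()) / cluster_means.std(ddof=0)
    ok = (z >= z_min - _Z_GUARD).all(axis=1)
    return sorted(int(c) for c in ok[ok].index)


def lr_score(
    norm_adata: ad.AnnData,
    labels: Sequence[str] | pd.Series,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Ligand-receptor co-expression score with a label-permutation null.

    score = mean expm1 ligand expression in the sender subtype times mean
    expm1 receptor expression in the receiver subtype; the p-value is the
    permutation tail probability (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    labels = np.asarray(labels)
    for name, subtype in (("sender", sender), ("receiver", receiver)):
        if subtype not in labels:
            raise ValueError(f"{name} subtype {subtype!r} absent from labels")
    names = pd.Index(norm_adata.var_names)
    for g in (ligand, receptor):
        if g not in names:
            raise ValueError(f"gene {g!r} absent from the matrix")
    X = densify(norm_adata.X)
    lig = np.expm1(X[:, names.get_loc(ligand)])
    rec = np.expm1(X[:, names.get_loc(receptor)])

    def score_for(lab: np.ndarray) -> float:
        return float(lig[lab == sender].mean() * rec[lab == receiver].mean())

    observed = score_for(labels)
    rng = np.random.default_rng(seed)
    null_ge = sum(
        score_for(rng.permutation(labels)) >= observed for _ in range(n_perm)
    )
    p = (1 + null_ge) / (1 + n_perm)
    return observed, p
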