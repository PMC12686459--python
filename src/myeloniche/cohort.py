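"""Patient stratification and survival analysis.

Patients are stratified either by hierarchical clustering of the
patient-patient correlation of their deconvolved subtype compositions
(complete linkage on 1 - Pearson distance), by a median split on the
combined abundance of chosen subtypes, or by a summed-signature expression
split. Survival differences between strata are quantified with the
Kaplan-Meier estimator, the log-rank test, and a two-group Cox proportional
hazards model (Newton-Raphson on the Breslow partial likelihood, Wald
confidence interval and p-value).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "presence_filter",
    "composition_correlation",
    "hierarchical_stratify",
    "median_split",
    "signature_split",
    "km_curve",
    "logrank",
    "cox_hr",
]


def presence_filter(P: pd.DataFrame, subtypes: Sequence[str]) -> pd.DataFrame:
    """Drop patients whose estimated total abundance of ``subtypes`` is zero.

    Mirrors excluding samples that lack the analyzed lineage before
    stratification.
    """
    total = P[list(subtypes)].sum(axis=1)
    removed = int((total <= 0).sum())
    if removed:
        warnings.warn(f"excluding {removed} samples with zero estimated target abundance")
    return P[total > 0]


def composition_correlation(P: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Patient x patient correlation of subtype-composition rows."""
    if len(P) < 3:
        raise ValueError("need at least 3 patients")
    constant = P.index[P.nunique(axis=1) <= 1]
    if len(constant):
        warnings.warn(f"excluding patients with constant composition: {list(constant)}")
        P = P.drop(index=constant)
    corr = P.T.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_stratify(corr: pd.DataFrame, k: int) -> pd.Series:
    """Agglomerative clustering on distance 1 - r, complete linkage, cut at k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(corr):
        raise ValueError("k exceeds the number of patients")
    dist = 1.0 - corr.values
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=corr.index, name="stratum")


def median_split(P: pd.DataFrame, subtypes: Sequence[str]) -> pd.Series:
    """High/low split on the combined abundance of the listed subtypes.

    "high" means strictly greater than the median; median-tied samples are
    labeled "low".
    """
    if not list(subtypes):
        raise ValueError("subtype list must be nonempty")
    combined = P[list(subtypes)].sum(axis=1)
    med = combined.median()
    labels = pd.Series(
        np.where(combined > med, "high", "low"), index=P.index, name="group"
    )
    if (labels == "low").all():
        warnings.warn("no sample above the median; all samples labeled low")
    return labels


def signature_split(
    bulk_expr: pd.DataFrame,
    genes: Sequence[str],
    cutoff: float | str = "median",
) -> tuple[pd.Series, pd.Series, tuple[np.ndarray, np.ndarray]]:
    """Split samples on the summed expression of a signature gene set.

    Returns (labels, per-sample scores, score histogram). The histogram
    supports choosing a manual numeric ``cutoff``; the default is the median.
    """
    present = [g for g in genes if g in bulk_expr.columns]
    if not present:
        raise ValueError("no signature genes present in the bulk table")
    score = bulk_expr[present].sum(axis=1).rename("signature_score")
    cut = score.median() if cutoff == "median" else float(cutoff)
    labels = pd.Series(
        np.where(score > cut, "high", "low"), index=bulk_expr.index, name="group"
    )
    hist = np.histogram(score.values, bins="auto")
    return labels, score, hist


# ---------------------------------------------------------------- survival


def _check_survival(table: pd.DataFrame) -> None:
    for col in ("time", "event", "group"):
        if col not in table.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    if (table["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not set(table["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")


def km_curve(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve for one group.

    Returns a step function as a DataFrame (time, survival) with steps at
    event times only, starting from S(0) = 1.
    """
    _check_survival(table)
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], sub["event"])
    surv = kmf.survival_function_["KM_estimate"]
    event_times = np.unique(sub.loc[sub["event"] == 1, "time"])
    times = np.concatenate([[0.0], event_times])
    return pd.DataFrame({"time": times, "survival": surv.loc[times].values})


def logrank(table: pd.DataFrame) -> tuple[float, float]:
    """Log-rank test across all groups; returns (chi2, p)."""
    _check_survival(table)
    if table["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if table["event"].sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(table["time"], table["group"], table["event"])
    return float(res.test_statistic), float(res.p_value)


def _cox_newton(time: np.ndarray, event: np.ndarray, x: np.ndarray, max_iter: int = 100):
    """Newton-Raphson on the Breslow partial likelihood, single covariate."""
    order = np.argsort(-time, kind="stable")  # descending: cumulative risk sets
    t_s, e_s, x_s = time[order], event[order], x[order]
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x_s)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w * x_s)
        S2 = np.cumsum(w * x_s**2)
        # risk set of subject i (sorted descending) = subjects with time >= t_i,
        # i.e. the cumulative sums up to the last index sharing t_i
        last = np.searchsorted(-t_s, -t_s, side="right") - 1
        ev = e_s == 1
        idx = last[ev]
        U = float((x_s[ev] - S1[idx] / S0[idx]).sum())
        I = float((S2[idx] / S0[idx] - (S1[idx] / S0[idx]) ** 2).sum())
        if I <= 0:
            raise ValueError("non-identifiable model (no information)")
        step = U / I
        beta += step
        if abs(beta) > 50:
            raise ValueError("monotone likelihood: complete separation between groups")
        if abs(step) < 1e-12:
            return beta, I
    raise ValueError("Cox Newton-Raphson failed to converge in 100 iterations")


def cox_hr(
    table: pd.DataFrame, reference_group: str
) -> tuple[float, tuple[float, float], float]:
    """Two-group Cox proportional hazards fit.

    Returns (hazard ratio of the non-reference group vs ``reference_group``,
    95% Wald CI, Wald p-value). Breslow tie handling.
    """
    _check_survival(table)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("cox_hr requires exactly 2 groups")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    other = next(g for g in groups if g != reference_group)
    for g in groups:
        if table.loc[table["group"] == g, "event"].sum() == 0:
            raise ValueError(f"group {g!r} has no events")
    x = (table["group"] == other).to_numpy(dtype=float)
    beta, info = _cox_newton(
        table["time"].to_numpy(dtype=float), table["event"].to_numpy(dtype=int), x
    )
    se = 1.0 / np.sqrt(info)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return hr, ci, p
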