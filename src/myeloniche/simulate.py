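"""Synthetic data generators carrying ground truth for every downstream stage.

The generators emulate the statistical structure the analysis assumes:

* single-cell counts with discrete subtypes defined by marker programs and an
  optional continuous early->late lineage gradient (negative-binomial noise,
  log-normal gene baselines and library sizes);
* bulk samples that are noisy mixtures of subtype reference profiles with
  known Dirichlet proportions;
* spatial spot grids with a planted niche block co-enriching designated
  subtypes and a marker program (Poisson counts given composition);
* survival cohorts with group-dependent exponential hazards;
* mouse-human ortholog tables with controllable dropout and 2:1 entries.

Every generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SubtypeSpec",
    "LineageSpec",
    "ScSimConfig",
    "NicheBlock",
    "SpatialSimConfig",
    "GroundTruth",
    "simulate_sc",
    "simulate_bulk",
    "simulate_spatial",
    "simulate_survival",
    "simulate_ortholog_table",
]


# ---------------------------------------------------------------- configs


@dataclass
class SubtypeSpec:
    """A discrete cell subtype with a marker program.

    ``marker_genes`` are integer gene indices into the simulated matrix;
    ``marker_fold`` multiplies the markers' mean expression inside the subtype.
    """

    name: str
    n_cells: int
    marker_genes: Sequence[int] = ()
    marker_fold: float = 1.0


@dataclass
class LineageSpec:
    """A continuous early->late gradient overlaid on the first cells.

    The first ``n_gradient_cells`` cells receive a pseudotime t ~ U(0,1);
    early markers are scaled by ``1 + (fold-1)*(1-t)`` and late markers by
    ``1 + (fold-1)*t``, so an early cell looks marker-high in the early
    program and vice versa.
    """

    early_markers: Sequence[int]
    late_markers: Sequence[int]
    n_gradient_cells: int
    fold: float = 8.0


@dataclass
class ScSimConfig:
    n_cells: int
    n_genes: int
    subtypes: Sequence[SubtypeSpec]
    lineage: LineageSpec | None = None
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.4
    libsize_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if sum(s.n_cells for s in self.subtypes) != self.n_cells:
            raise ValueError("subtype cell counts must sum to n_cells")
        seen: set[int] = set()
        marker_lists = [list(s.marker_genes) for s in self.subtypes]
        if self.lineage is not None:
            marker_lists += [list(self.lineage.early_markers), list(self.lineage.late_markers)]
        for genes in marker_lists:
            gset = set(genes)
            if gset & seen:
                raise ValueError("marker gene lists must be disjoint")
            seen |= gset
        if seen and max(seen) >= self.n_genes:
            raise ValueError("marker gene index exceeds n_genes")
        if self.lineage is not None and self.lineage.n_gradient_cells > self.n_cells:
            raise ValueError("n_gradient_cells exceeds n_cells")
        if self.baseline_log_sd <= 0 or self.nb_dispersion <= 0 or self.libsize_log_sd < 0:
            raise ValueError("noise parameters out of range")


@dataclass
class NicheBlock:
    """An axis-aligned grid block with co-enriched subtypes and markers."""

    x0: int
    y0: int
    x1: int
    y1: int
    enriched_subtypes: Sequence[str]
    niche_marker_genes: Sequence[str] = ()
    enrichment_fold: float = 6.0


@dataclass
class SpatialSimConfig:
    grid_w: int
    grid_h: int
    niche_blocks: Sequence[NicheBlock] = ()
    background_dirichlet_alpha: float | Sequence[float] = 10.0
    depth_mean: int = 5000
    seed: int = 0

    def validate(self, subtypes: Sequence[str]) -> None:
        if self.grid_w <= 0 or self.grid_h <= 0:
            raise ValueError("empty grid")
        for b in self.niche_blocks:
            if not (0 <= b.x0 <= b.x1 < self.grid_w and 0 <= b.y0 <= b.y1 < self.grid_h):
                raise ValueError("niche block outside grid")
            if b.enrichment_fold <= 1:
                raise ValueError("enrichment_fold must exceed 1")
            missing = set(b.enriched_subtypes) - set(subtypes)
            if missing:
                raise ValueError(f"unknown enriched subtypes: {sorted(missing)}")


@dataclass
class GroundTruth:
    """Everything a recovery test needs, serialized alongside the data."""

    cell_labels: pd.Series | None = None
    pseudotime: pd.Series | None = None
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    spot_proportions: pd.DataFrame | None = None
    region_labels: pd.Series | None = None
    survival_group_hazard: dict[str, float] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


# ---------------------------------------------------------------- single cell


def simulate_sc(cfg: ScSimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a cells x genes count matrix under the subtype/lineage model.

    Counts are negative binomial with mean ``libsize_c * baseline_g * fold_cg``
    and a single shared dispersion (variance mu + dispersion*mu^2), sampled as
    a gamma-Poisson mixture.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    libsize = rng.lognormal(0.0, cfg.libsize_log_sd, cfg.n_cells) if cfg.libsize_log_sd > 0 else np.ones(cfg.n_cells)

    labels = np.concatenate([np.repeat(s.name, s.n_cells) for s in cfg.subtypes])
    fold = np.ones((cfg.n_cells, cfg.n_genes))
    start = 0
    for s in cfg.subtypes:
        idx = np.asarray(list(s.marker_genes), dtype=int)
        if idx.size:
            fold[start : start + s.n_cells, idx] *= s.marker_fold
        start += s.n_cells

    pseudotime = np.full(cfg.n_cells, np.nan)
    if cfg.lineage is not None:
        lin = cfg.lineage
        t = rng.uniform(0.0, 1.0, lin.n_gradient_cells)
        pseudotime[: lin.n_gradient_cells] = t
        early = np.asarray(list(lin.early_markers), dtype=int)
        late = np.asarray(list(lin.late_markers), dtype=int)
        rows = np.arange(lin.n_gradient_cells)
        if early.size:
            fold[np.ix_(rows, early)] *= (1 + (lin.fold - 1) * (1 - t))[:, None]
        if late.size:
            fold[np.ix_(rows, late)] *= (1 + (lin.fold - 1) * t)[:, None]

    mu = libsize[:, None] * baseline[None, :] * fold
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu * cfg.nb_dispersion)
    counts = rng.poisson(lam)

    obs = pd.DataFrame(
        {"subtype": labels, "pseudotime": pseudotime},
        index=[f"CELL{i:05d}" for i in range(cfg.n_cells)],
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs)
    adata.var_names = genes

    marker_sets = {
        s.name: [genes[i] for i in s.marker_genes] for s in cfg.subtypes if len(s.marker_genes)
    }
    if cfg.lineage is not None:
        marker_sets["early"] = [genes[i] for i in cfg.lineage.early_markers]
        marker_sets["late"] = [genes[i] for i in cfg.lineage.late_markers]

    truth = GroundTruth(
        cell_labels=obs["subtype"].copy(),
        pseudotime=obs["pseudotime"].copy(),
        marker_sets=marker_sets,
    )
    return adata, truth


# ---------------------------------------------------------------- bulk


def simulate_bulk(
    ref: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha: Sequence[float],
    depth: int = 1_000_000,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Mix reference profiles into bulk samples with known proportions.

    ``ref`` is subtypes x genes. Each sample's expected expression is
    ``proportions @ ref`` rescaled to ``depth`` total counts, perturbed by
    multiplicative log-normal noise of coefficient of variation ``noise_cv``.
    With noise the result is rounded to integer counts; at ``noise_cv == 0``
    the exact expected mixture is returned so linear recovery is testable to
    machine precision.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (ref.shape[0],):
        raise ValueError("dirichlet_alpha length must match number of subtypes")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n_samples)
    expected = props @ ref.values
    expected = expected * (depth / expected.sum(axis=1, keepdims=True))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = rng.lognormal(-sigma**2 / 2, sigma, expected.shape)
        counts = np.rint(expected * factors)
    else:
        counts = expected
    obs = pd.DataFrame(index=[f"SAMPLE{i:04d}" for i in range(n_samples)])
    adata = ad.AnnData(X=counts, obs=obs)
    adata.var_names = list(ref.columns)
    prop_df = pd.DataFrame(props, index=obs.index, columns=ref.index)
    return adata, prop_df


# ---------------------------------------------------------------- spatial


def simulate_spatial(
    ref: pd.DataFrame, cfg: SpatialSimConfig
) -> tuple[ad.AnnData, pd.DataFrame, GroundTruth]:
    """Lay spots on a grid with a background Dirichlet composition and planted
    niche blocks.

    Inside a block, the Dirichlet weights of the enriched subtypes are
    multiplied by ``enrichment_fold`` before sampling the spot's composition,
    and the block's ``niche_marker_genes`` are additionally multiplied by the
    same fold in the spot's expected expression. Counts are Poisson at
    ``depth_mean`` expected total counts per spot.
    """
    subtypes = list(ref.index)
    cfg.validate(subtypes)
    rng = np.random.default_rng(cfg.seed)
    K = len(subtypes)
    alpha0 = np.broadcast_to(
        np.asarray(cfg.background_dirichlet_alpha, dtype=float), (K,)
    ).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("background_dirichlet_alpha must be positive")

    xs, ys = np.meshgrid(np.arange(cfg.grid_w), np.arange(cfg.grid_h), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    n_spots = xs.size

    region = np.zeros(n_spots, dtype=int)
    props = np.empty((n_spots, K))
    gene_fold = np.ones((n_spots, ref.shape[1]))
    gene_index = {g: j for j, g in enumerate(ref.columns)}
    for b_id, b in enumerate(cfg.niche_blocks, start=1):
        inside = (xs >= b.x0) & (xs <= b.x1) & (ys >= b.y0) & (ys <= b.y1)
        region[inside] = b_id
        cols = [gene_index[g] for g in b.niche_marker_genes]
        if cols:
            gene_fold[np.ix_(inside, cols)] *= b.enrichment_fold

    for s in range(n_spots):
        alpha = alpha0.copy()
        if region[s] > 0:
            b = cfg.niche_blocks[region[s] - 1]
            for name in b.enriched_subtypes:
                alpha[subtypes.index(name)] *= b.enrichment_fold
        props[s] = rng.dirichlet(alpha)

    expected = props @ ref.values
    expected = expected * (cfg.depth_mean / expected.sum(axis=1, keepdims=True))
    expected = expected * gene_fold
    counts = rng.poisson(expected)

    spot_ids = [f"SPOT{i:05d}" for i in range(n_spots)]
    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)))
    adata.obs_names = spot_ids
    adata.var_names = list(ref.columns)
    coords = pd.DataFrame({"spot_id": spot_ids, "x": xs, "y": ys}).set_index("spot_id")
    truth = GroundTruth(
        spot_proportions=pd.DataFrame(props, index=spot_ids, columns=subtypes),
        region_labels=pd.Series(region, index=spot_ids, name="region"),
    )
    return adata, coords, truth


# ---------------------------------------------------------------- survival


def simulate_survival(
    n_per_group: int | Mapping[str, int],
    hazard_rates: Mapping[str, float],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times per group with independent exponential censoring.

    Returns a table with columns ``time``, ``event`` (1 = observed), ``group``.
    """
    if not hazard_rates:
        raise ValueError("hazard_rates must name at least one group")
    if any(r <= 0 for r in hazard_rates.values()):
        raise ValueError("hazard rates must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    sizes = (
        {g: n_per_group for g in hazard_rates}
        if isinstance(n_per_group, int)
        else dict(n_per_group)
    )
    if any(n <= 0 for n in sizes.values()):
        raise ValueError("empty groups are not allowed")
    rng = np.random.default_rng(seed)
    rows = []
    for group, rate in hazard_rates.items():
        n = sizes[group]
        event_t = rng.exponential(1.0 / rate, n)
        if censor_rate > 0:
            censor_t = rng.exponential(1.0 / censor_rate, n)
        else:
            censor_t = np.full(n, np.inf)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        rows.append(pd.DataFrame({"time": time, "event": event, "group": group}))
    table = pd.concat(rows, ignore_index=True)
    table.index = [f"SUBJ{i:05d}" for i in range(len(table))]
    return table


# ---------------------------------------------------------------- orthologs


def _title_case(symbol: str) -> str:
    return symbol[:1].upper() + symbol[1:].lower()


def simulate_ortholog_table(
    genes: Sequence[str],
    prefix_transform: Callable[[str], str] | None = None,
    drop_fraction: float = 0.0,
    duplicate_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a mouse-human ortholog table from human symbols.

    By default the mouse symbol is the title-cased human symbol (the usual
    human SPP1 -> mouse Spp1 convention). ``drop_fraction`` removes that share
    of genes from the table entirely; ``duplicate_fraction`` gives that share
    of the remaining genes a second mouse ortholog (suffix ``-ps``), producing
    2:1 entries.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    transform = prefix_transform or _title_case
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_drop = int(round(drop_fraction * len(genes)))
    dropped = set(rng.choice(len(genes), size=n_drop, replace=False)) if n_drop else set()
    kept = [g for i, g in enumerate(genes) if i not in dropped]
    rows = [(transform(g), g) for g in kept]
    n_dup = int(round(duplicate_fraction * len(kept)))
    if n_dup:
        dup_idx = rng.choice(len(kept), size=n_dup, replace=False)
        rows += [(transform(kept[i]) + "-ps", kept[i]) for i in sorted(dup_idx)]
    return pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol"])
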