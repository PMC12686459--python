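# myeloniche

Tumors recruit and reprogram myeloid cells — neutrophils, monocytes and
macrophages — into subtypes with opposing roles, and in triple-negative
breast cancer (TNBC) two of them matter clinically: *SPP1*-high macrophages
and *VEGFA*-high neutrophils, which co-localize with *APLN*-expressing
endothelial tip cells in hypoxic, angiogenic tissue niches and predict poor
survival. `myeloniche` is a tested, reusable implementation of the
quantitative pipeline behind that kind of analysis, for computational
biologists working with single-cell, bulk and spatial transcriptomics of
the tumor microenvironment:

- **QC and normalization** — cell/gene/spot count filters with strict
  threshold semantics, total-count scaling with log1p, binned-dispersion
  highly variable gene selection.
- **Marker discovery** — one-vs-rest Wilcoxon rank-sum tests per gene with
  Benjamini–Hochberg correction, ribosomal/mitochondrial exclusion, a 10%
  within-cluster detection filter, and the ranking score
  `ranking = (−ln p_adj) × log2FC` that orders subtype signatures.
- **Gene-set scoring** — per-cell rank-AUC (normalized recovery-curve area
  over the top fraction of each cell's expression ranking), bin-matched
  control scoring, and a maturation score (late-program AUC minus
  early-program AUC) that orders cells along a differentiation gradient.
- **Deconvolution** — subtype reference profiles from labeled single-cell
  data, and nonnegative least-squares estimation of subtype proportions in
  bulk samples and Visium-style spots.
- **Spatial niche analysis** — subtype colocalization, abundance–signature
  correlation under a dual-significance rule (spot-level p and correlation p
  both < 0.05), k-means region clustering of spot compositions, relative
  (z-score) niche calling, and a permutation-tested ligand–receptor score.
- **Cohort analysis** — stratification by composition correlation +
  hierarchical clustering, median or signature splits, Kaplan–Meier curves,
  log-rank tests, and a two-group Cox model (Breslow partial likelihood).
- **Cross-species mapping** — ortholog translation of signatures and joint
  human/mouse subtype clustering on median-normalized average expression.
- **Synthetic data** — generators for all of the above with full ground
  truth (subtype labels, pseudotime, spot compositions, region labels,
  hazard rates), so every stage has a closed recovery test.

Counts travel as `AnnData` (CellRanger-style Matrix-Market on disk), gene
sets as GMT, and tables as pandas DataFrames / CSV.

## Worked example

Recover a planted angiogenic-niche block from simulated spatial data:

```python
import numpy as np, pandas as pd
from myeloniche import preprocess, scoring
from myeloniche.deconvolution import decompose_matrix
from myeloniche.niche import call_niche, cluster_spots
from myeloniche.simulate import NicheBlock, SpatialSimConfig, simulate_spatial

rng = np.random.default_rng(0)
genes = [f"G{j:05d}" for j in range(200)]
ref = pd.DataFrame(rng.lognormal(0, 1, (5, 200)),
                   index=[f"S{k}" for k in range(5)], columns=genes)

cfg = SpatialSimConfig(
    grid_w=32, grid_h=32,
    niche_blocks=[NicheBlock(5, 5, 14, 14, ["S0", "S1"], genes[190:195], 6.0)],
    seed=0)
spots, coords, truth = simulate_spatial(ref, cfg)

est = decompose_matrix(spots, ref)              # spot x subtype proportions
rc = cluster_spots(est, k=2, seed=0)            # composition regions
sig = scoring.bin_control_score(
    preprocess.lognormalize(spots), genes[190:195], seed=0).to_frame("niche_sig")
print(call_niche(rc, est, sig, ["S0", "S1"], ["niche_sig"]))
print(rc.cluster_composition.round(3))
```

Output:

```
[1]
            S0     S1     S2     S3     S4
cluster
0        0.196  0.197  0.203  0.201  0.203
1        0.406  0.383  0.067  0.087  0.057
```

Cluster 1 is called as the niche: it is the only region whose mean
abundance of both enriched subtypes *and* the niche marker program sits at
least one standard deviation above the across-cluster mean — here it holds
roughly 0.79 combined S0+S1 proportion against 0.39 in the background, and
it coincides with the planted 10×10 block (adjusted Rand index 0.99
against the ground-truth region labels).

A thin CLI wraps the same functions (`myeloniche simulate sc ...`,
`myeloniche qc ...`, `myeloniche score ...`, `myeloniche deconv ...`,
`myeloniche survive ...`); run `myeloniche --help` for the commands.

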