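import numpy as np
import pandas as pd
import pytest

from myeloniche import preprocess
from myeloniche.simulate import ScSimConfig, SubtypeSpec, simulate_sc


@pytest.fixture(scope="session")
def three_subtype_sim():
    """3 subtypes x 200 cells, 50 markers each at fold 8 (seed 0)."""
    cfg = ScSimConfig(
        n_cells=600,
        n_genes=1000,
        subtypes=[
            SubtypeSpec("A", 200, list(range(0, 50)), 8.0),
            SubtypeSpec("B", 200, list(range(50, 100)), 8.0),
            SubtypeSpec("C", 200, list(range(100, 150)), 8.0),
        ],
        seed=0,
    )
    return simulate_sc(cfg)


@pytest.fixture(scope="session")
def three_subtype_norm(three_subtype_sim):
    adata, truth = three_subtype_sim
    return preprocess.lognormalize(adata), truth


@pytest.fixture(scope="session")
def reference_profiles():
    """5 random positive subtype profiles over 200 genes."""
    rng = np.random.default_rng(1)
    return pd.DataFrame(
        rng.lognormal(0, 1, (5, 200)),
        index=[f"S{k}" for k in range(5)],
        columns=[f"G{j:05d}" for j in range(200)],
    )
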