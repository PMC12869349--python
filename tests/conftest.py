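import numpy as np
import pandas as pd
import pytest

from tme_ecotypes import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_samples=20, n_cells_per_sample=(200, 500), seed=11, normal_fraction=0.2
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_cells(gene_counts, sample_id="s1", **overrides):
    """Hand-built cell table with nominal metrics except where overridden."""
    n = len(gene_counts)
    base = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i}" for i in range(n)],
            "sample_id": sample_id,
            "umi_count": 5000,
            "gene_count": gene_counts,
            "housekeeping_count": 80,
            "mito_fraction": 0.05,
        }
    )
    for col, vals in overrides.items():
        base[col] = vals
    return base
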