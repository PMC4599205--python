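import numpy as np
import pandas as pd
import pytest

import zicbench as z


def make_count_matrix(counts, groups, gene_ids=None):
    """Small helper to build a CountMatrix from an array and group labels."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    design = pd.Series(list(groups), index=pd.Index(sample_ids, name="sample_id"))
    return z.CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        design,
    )


@pytest.fixture(scope="session")
def pool():
    return z.make_surrogate_pool(4000, seed=7)


@pytest.fixture(scope="session")
def small_sim(pool):
    """One simulated dataset with zero-injected DE genes (400 features)."""
    cfg = z.SimulationConfig(n_features=400, seed=5)
    return z.simulate_dataset(pool, cfg), cfg


@pytest.fixture(scope="session")
def null_sim(pool):
    """Pure-null simulation (no zero injection), 600 features."""
    cfg = z.SimulationConfig(n_features=600, frac_zero_de=0.0, seed=9)
    return z.simulate_dataset(pool, cfg), cfg
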