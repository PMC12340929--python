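import numpy as np
import pandas as pd
import pytest

from cortexpheno.config import CountsConfig, SimConfig
from cortexpheno.containers import CountMatrix


@pytest.fixture
def null_counts_config():
    """Study-sized null design: 5 vs 5 samples, no planted DE, one batch."""
    def make(seed: int, n_genes: int = 2000) -> SimConfig:
        cfg = SimConfig(seed=seed)
        cfg.counts = CountsConfig(n_genes=n_genes, fraction_de=0.0, n_batches=1)
        return cfg
    return make


@pytest.fixture
def small_nucleus_matrix():
    """Hand-sized nucleus-level matrix: 4 genes, 6 nuclei, 3 samples, 2 cell types."""
    genes = ["gA", "gB", "gC", "gD"]
    counts = np.array(
        [
            [2, 3, 1, 0, 5, 2],
            [0, 1, 4, 4, 0, 1],
            [7, 0, 2, 1, 1, 3],
            [1, 1, 1, 1, 1, 1],
        ]
    )
    meta = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "genotype": ["WT", "WT", "HET", "HET", "WT", "WT"],
            "batch": ["b1", "b1", "b1", "b1", "b2", "b2"],
            "cell_type2": ["exc", "inh", "exc", "inh", "exc", "exc"],
        },
        index=pd.Index([f"n{i}" for i in range(6)], name="unit"),
    )
    return CountMatrix(genes, counts, meta)
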