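import numpy as np
import pandas as pd
import pytest

from dargtools import ExpressionMatrix, normalize


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    """4 genes x 3 observations with easy-to-track integer counts."""
    values = np.array(
        [
            [5, 0, 2],
            [0, 3, 1],
            [1, 1, 0],
            [4, 0, 7],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["GFAP", "VIM", "SOX2", "NES"],
        obs_ids=["c1", "c2", "c3"],
        values=values,
        layer="raw_counts",
    )


@pytest.fixture
def toy_normalized(toy_counts) -> ExpressionMatrix:
    return normalize(toy_counts, scale_factor=10_000, log_base=2)


def random_count_matrix(rng, n_genes=30, n_obs=20, density=0.4) -> ExpressionMatrix:
    counts = rng.poisson(2.0, size=(n_genes, n_obs)) * (
        rng.random((n_genes, n_obs)) < density
    )
    # ensure every observation is non-empty
    for j in range(n_obs):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_genes), j] = 1
    return ExpressionMatrix(
        gene_ids=[f"G{i:03d}" for i in range(n_genes)],
        obs_ids=[f"obs{j:03d}" for j in range(n_obs)],
        values=counts,
        layer="raw_counts",
    )


@pytest.fixture
def spot_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "obs_id": ["s1", "s2", "s3", "s4"],
            "x": [0, 1, 0, 1],
            "y": [0, 0, 1, 1],
            "tissue": ["WM", "WM", "GM", "GM"],
            "niche": ["LC", "LR", "GM1", "GM2"],
            "sample_id": ["p1", "p1", "p2", "p2"],
            "group": ["MS", "MS", "Ctrl", "Ctrl"],
        }
    )
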