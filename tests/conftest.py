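import numpy as np
import pandas as pd
import pytest

from brafsig import ExpressionMatrix, SimulationConfig
from brafsig.simulate import simulate_cellline_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale bundle: 300 genes, 60 lines, default planted effect."""
    return SimulationConfig(seed=11, n_genes=300, n_samples=60)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cellline_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_matrix(values, genes=None, samples=None, scale="log2") -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), scale)
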