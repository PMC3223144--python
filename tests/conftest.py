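import numpy as np
import pandas as pd
import pytest

from seedscape.expression import ExpressionMatrix
from seedscape.pipeline import PipelineConfig, run_all
from seedscape.synthetic import SyntheticConfig

TEST_SEED = 11


@pytest.fixture(scope="session")
def default_pipeline():
    """One full default-condition run of the chain, shared across tests."""
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(rng_seed=TEST_SEED), rng_seed=TEST_SEED
    )
    return run_all(cfg)


@pytest.fixture(scope="session")
def default_dataset(default_pipeline):
    return default_pipeline.dataset


def make_matrix(values, columns, index=None) -> ExpressionMatrix:
    """Small helper: ExpressionMatrix from a 2-D array and array ids."""
    values = np.asarray(values, dtype=float)
    if index is None:
        index = [f"f{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=index, columns=columns))


def two_group_columns(n_per_group=3):
    return [f"A_r{i+1}" for i in range(n_per_group)] + [
        f"B_r{i+1}" for i in range(n_per_group)
    ]
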