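import numpy as np
import pandas as pd
import pytest

import brmtls as b
from brmtls.expression import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, genes=None, samples=None, unit="counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


@pytest.fixture(scope="session")
def default_cohort():
    """Default five-site synthetic cohort at a fixed seed."""
    cfg = b.SimulationConfig(seed=1)
    counts, lengths, truth = b.generate_bulk_cohort(cfg)
    return counts, lengths, truth
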