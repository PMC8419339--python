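import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from leukodx import SyntheticConfig, abl1_normalize, generate_expression, table2_variants


@pytest.fixture(scope="session")
def table2():
    return table2_variants()


@pytest.fixture(scope="session")
def default_cohort():
    """Generator defaults at n=20/group, seed 0: (matrix, labels, truth)."""
    return generate_expression(SyntheticConfig(n_per_group=20, seed=0))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    matrix, labels, truth = default_cohort
    return abl1_normalize(matrix, "ABL1", 100.0), labels, truth


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples, handy for IO and scoring edge cases."""
    return pd.DataFrame(
        [[400.0, 380.0, 4.0, 5.0], [2.0, 3.0, 150.0, 160.0], [100.0, 100.0, 100.0, 100.0]],
        index=pd.Index(["MPO", "PAX5", "ABL1"], name="gene"),
        columns=["A1", "A2", "B1", "B2"],
    )


@pytest.fixture()
def tiny_labels():
    return pd.Series(
        ["AML", "AML", "B-ALL", "B-ALL"],
        index=["A1", "A2", "B1", "B2"],
        name="label",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
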