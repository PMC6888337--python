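import numpy as np
import pandas as pd
import pytest

from litsig.expression import ExpressionMatrix


@pytest.fixture
def two_group_matrix():
    """Deterministic 6-gene x 8-sample matrix with two labeled groups."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(1, 7)]
    samples = [f"S{i}" for i in range(1, 9)]
    values = pd.DataFrame(rng.normal(7.0, 1.0, size=(6, 8)),
                          index=genes, columns=samples)
    groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
    return ExpressionMatrix(values, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
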