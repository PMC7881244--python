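import numpy as np
import pandas as pd
import pytest

from tmesig.io import ExpressionMatrix


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return make_matrix([[1.0, 2.0], [3.0, 4.0]], ["gA", "gB"], ["s1", "s2"])


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(7, 1, size=(30, 12)))
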