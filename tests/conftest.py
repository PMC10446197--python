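import numpy as np
import pandas as pd
import pytest

from cidrgn import ExpressionDataset, SubnetworkSpec


@pytest.fixture
def small_dataset():
    """20 cell lines × 12 genes, two phenotypes, reproducible."""
    rng = np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(12)]
    df = pd.DataFrame(rng.standard_normal((20, 12)), columns=genes,
                      index=[f"c{i:02d}" for i in range(20)])
    return ExpressionDataset(df, ["A"] * 10 + ["B"] * 10)


@pytest.fixture
def small_subnetworks():
    return [
        SubnetworkSpec("s1", [f"g{i:02d}" for i in range(0, 5)]),
        SubnetworkSpec("s2", [f"g{i:02d}" for i in range(5, 10)]),
    ]


def random_instance(seed, n=16, g=5):
    """A small random two-phenotype instance used by the oracle suite."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, g))
    in_a = np.zeros(n, dtype=bool)
    in_a[: n // 2] = True
    in_b = ~in_a
    coef_a = rng.standard_normal((g, g)) * (rng.random((g, g)) < 0.5)
    coef_b = rng.standard_normal((g, g)) * (rng.random((g, g)) < 0.5)
    np.fill_diagonal(coef_a, 0.0)
    np.fill_diagonal(coef_b, 0.0)
    return values, in_a, in_b, coef_a, coef_b
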