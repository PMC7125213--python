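import numpy as np
import pandas as pd
import pytest

from dispervar import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(values: np.ndarray, n_case: int, genes=None) -> ExpressionMatrix:
    """Wrap a genes x samples array; the first n_case columns are cases."""
    n_genes, n_samples = values.shape
    genes = genes or [f"gene_{i:04d}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    labels = pd.Series(["case"] * n_case + ["control"] * (n_samples - n_case), index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), labels=labels
    )
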