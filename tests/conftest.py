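import numpy as np
import pandas as pd
import pytest

from refrank import CtDataset, ExpressionMatrix


def make_ct(matrix, genes=None, samples=None, group="OP") -> CtDataset:
    """Build a replicate-collapsed CtDataset from a 2D genes × samples array."""
    matrix = np.asarray(matrix, dtype=float)
    g, n = matrix.shape
    genes = genes or [f"g{i + 1}" for i in range(g)]
    samples = samples or [f"s{j + 1}" for j in range(n)]
    return CtDataset(list(genes), list(samples), matrix[:, :, None],
                     group=group)


def make_matrix(values, genes=None, stages=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = genes or [f"g{i + 1}" for i in range(g)]
    stages = stages or [f"st{j + 1}" for j in range(n)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=stages))


@pytest.fixture
def random_ct():
    """Factory for random CT matrices in the plausible cycle range."""

    def _make(seed: int, g: int = 6, n: int = 9, group: str = "OP") -> CtDataset:
        rng = np.random.default_rng(seed)
        base = rng.uniform(18.0, 30.0, size=(g, 1))
        return make_ct(base + rng.normal(0.0, 1.0, size=(g, n)), group=group)

    return _make
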