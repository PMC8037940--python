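import numpy as np
import pandas as pd
import pytest

from fluoropanel import GenotypeMatrix, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_matrix(data: dict, samples: list[str] | None = None) -> GenotypeMatrix:
    """Dosage matrix from {variant_id: [dosages]} with NaN for missing."""
    n = len(next(iter(data.values())))
    index = pd.Index(samples or [f"S{i:03d}" for i in range(n)], name="sample_id")
    return GenotypeMatrix(pd.DataFrame(data, index=index, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
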