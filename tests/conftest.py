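import numpy as np
import pandas as pd
import pytest

from quiescentome import ExpressionMatrix, SimConfig, simulate
from quiescentome.synthdata import generate_expression


def small_config(seed=1, **kw):
    """A fast, fully planted study configuration for tests."""
    defaults = dict(
        n_genes=500, seed=seed,
        n_de_per_contrast={"hlf-vs-uM": 30, "uM_LPS-vs-uM": 40},
        module_size=8, n_gene_sets=15, set_size_range=(8, 30),
        n_physical_edges=30, n_soluble_edges=20,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def study():
    return simulate(small_config(seed=11))


@pytest.fixture(scope="session")
def expr_truth():
    return generate_expression(small_config(seed=7))


def toy_matrix(values, conditions, donors, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    v = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame({"condition": conditions, "donor": donors}, index=samples)
    return ExpressionMatrix(v, meta)
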