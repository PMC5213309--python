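import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tamnet.containers import ExpressionMatrix, SampleDesign
from tamnet.simulate import default_config, generate_dataset
from tamnet import preprocess

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_design(n_donors=4, conditions=("TPC1", "RPMI"), times=("4h", "24h")):
    rows = []
    for c in conditions:
        for t in times:
            for d in range(1, n_donors + 1):
                rows.append((f"{c}_{t}_D{d}", c, t, f"D{d}"))
    tab = pd.DataFrame(rows, columns=["sample", "condition", "time", "donor"])
    return SampleDesign(tab.set_index("sample"))


def make_log_matrix(values, genes=None, design=None):
    """log2cpm-scale matrix from a raw gene x sample array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = design.samples if design is not None else [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), scale="log2cpm")


@pytest.fixture(scope="session")
def small_design():
    return make_design()


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the default synthetic world, shared across tests."""
    cfg = default_config(seed=11)
    matrix, design, truth = generate_dataset(cfg)
    return matrix, design, truth


@pytest.fixture(scope="session")
def default_log_expr(default_dataset):
    matrix, design, _ = default_dataset
    filtered = preprocess.filter_present(matrix, design)
    return preprocess.normalize_log_cpm(filtered), design
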