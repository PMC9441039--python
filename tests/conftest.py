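import numpy as np
import pandas as pd
import pytest

from cernet.expression import ExpressionMatrix
from cernet.simulate import SimulationConfig, generate_dataset

GROUPS_3V3 = {
    "CC_1": "CC", "CC_2": "CC", "CC_3": "CC",
    "GC_1": "GC", "GC_2": "GC", "GC_3": "GC",
}


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design: enough miRNAs for a meaningful overlap universe."""
    return SimulationConfig(
        n_mrna=400, n_lncrna=120, n_mirna=150, n_planted_triples=10, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def make_matrix(values, class_label="mRNA", lengths=None, samples=None):
    samples = samples or list(GROUPS_3V3)
    df = pd.DataFrame(values, columns=samples)
    df.index = [f"t{i}" for i in range(len(df))]
    lens = None
    if class_label != "miRNA":
        lens = pd.Series(lengths if lengths is not None else [1000.0] * len(df),
                         index=df.index)
    return ExpressionMatrix(
        values=df, class_label=class_label, groups=GROUPS_3V3, lengths=lens
    )


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(0)
    return make_matrix(rng.integers(10, 1000, size=(5, 6)).astype(float))
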