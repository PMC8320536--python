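import numpy as np
import pandas as pd
import pytest

from dpcnet import SyntheticConfig, simulate
from dpcnet.datatypes import ExpressionMatrix, MethylationMatrix, SampleGroups


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset with the default conditions, shared read-only."""
    return simulate.generate(SyntheticConfig(seed=7))


@pytest.fixture
def toy_groups():
    return SampleGroups(
        {"s1": "tumor", "s2": "tumor", "s3": "tumor", "s4": "tumor",
         "s5": "normal", "s6": "normal", "s7": "normal", "s8": "normal"}
    )


@pytest.fixture
def toy_expr(toy_groups):
    rng = np.random.default_rng(42)
    genes = ["A", "B", "C", "D"]
    vals = rng.gamma(2.0, 1.0, size=(4, 8))
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=list(toy_groups.labels)))


def make_methylation(site_rows: dict, site_gene: dict, samples: list[str]):
    return MethylationMatrix(
        pd.DataFrame(site_rows, index=samples).T,
        pd.Series(site_gene, name="gene"),
    )
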