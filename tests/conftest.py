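import numpy as np
import pandas as pd
import pytest

import metabodose as md


def make_table(values, genotypes, metabolites=None) -> md.AbundanceTable:
    """Build a table from a nested list; genotypes is one label per row."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    metabolites = metabolites or [f"met{j}" for j in range(m)]
    samples = [f"s{i}" for i in range(n)]
    return md.AbundanceTable(
        data=pd.DataFrame(values, index=samples, columns=metabolites),
        genotypes=pd.Series(list(genotypes), index=samples),
    )


@pytest.fixture
def small_table() -> md.AbundanceTable:
    """2 genotypes x 3 replicates x 4 metabolites, no missing values."""
    rng = np.random.default_rng(42)
    values = rng.lognormal(mean=5.0, sigma=0.3, size=(6, 4))
    return make_table(values, ["WT"] * 3 + ["hom"] * 3)


@pytest.fixture
def preprocessed():
    """Default synthetic table through the full preprocessing chain."""
    table, truth = md.generate(md.SimulationConfig(seed=11))
    table = md.normalize_tic(md.impute_missing(md.presence_filter(table)))
    return table, truth
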