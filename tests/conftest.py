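import numpy as np
import pandas as pd
import pytest

from mddpanel.cohort import CohortParams, generate_cohort
from mddpanel.de import CountMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at a reduced transcriptome size."""
    return generate_cohort(CohortParams(n_genes=300, seed=11))


@pytest.fixture()
def toy_counts():
    """3 genes x 4 samples with equal library sizes (easy hand arithmetic)."""
    df = pd.DataFrame(
        {
            "s1": [5, 0, 123],
            "s2": [5, 0, 123],
            "s3": [5, 0, 123],
            "s4": [5, 0, 123],
        },
        index=["gA", "gB", "gC"],
    )
    return CountMatrix(
        df,
        gene_lengths=pd.Series([2000, 1500, 1000], index=df.index),
        library_sizes=pd.Series([10, 10, 10, 10], index=df.columns, dtype=float),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
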