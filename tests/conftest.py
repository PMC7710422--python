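import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import panlandscape as pl

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from panlandscape.io_formats import GeneSampleMatrix


@pytest.fixture(scope="session")
def mini_bundle():
    """A small two-cancer cohort with the default planted effects."""
    cfg = pl.CohortConfig(
        cancer_types=("BRCA", "UCEC"),
        n_background_genes=30,
        n_tumor=20,
        n_normal=10,
        n_cell_lines=80,
        n_drugs=8,
        seed=7,
    )
    return pl.generate_cohort(cfg)


@pytest.fixture
def toy_counts():
    """Five stable genes anchor the size factors at 1; gene X carries an
    exact two-fold change with integer counts."""
    samples = [f"SYN-TT-{i:04d}-01A" for i in range(4)] + [
        f"SYN-TT-{i:04d}-11A" for i in range(4)
    ]
    data = {
        "S1": [50] * 8,
        "S2": [80] * 8,
        "S3": [120] * 8,
        "S4": [200] * 8,
        "S5": [1000] * 8,
        # tumor mean 200.5 = 2 * (normal mean 100) + 0.5 => log2 FC exactly 1
        "GX": [200, 200, 201, 201, 100, 100, 100, 100],
    }
    df = pd.DataFrame(data, index=samples).T.astype(float)
    df.columns = samples
    return GeneSampleMatrix(df, "raw_count")


def expression_from_counts(counts: GeneSampleMatrix) -> GeneSampleMatrix:
    """log2(count + 1), a monotone per-gene expression scale used when a
    test wants grouping to be independent of size-factor noise."""
    return GeneSampleMatrix(np.log2(counts.values + 1.0), "normalized_expression")
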