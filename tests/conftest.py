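"""Shared fixtures: tiny handmade inputs and cached synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from padsub import ExpressionMatrix, GeneSetCollection, simulate_cohort


@pytest.fixture(scope="session")
def tiny_expr() -> ExpressionMatrix:
    """12 genes x 12 samples in one dataset, reproducible."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(12)]
    samples = [f"s{j}" for j in range(12)]
    values = pd.DataFrame(rng.normal(5, 2, (12, 12)), index=genes, columns=samples)
    dataset_of = pd.Series("D1", index=samples)
    return ExpressionMatrix(values, dataset_of)


@pytest.fixture(scope="session")
def tiny_sets() -> GeneSetCollection:
    return GeneSetCollection({
        "top": ["g0", "g1", "g2", "g3", "g4"],
        "mixed": ["g1", "g5", "g9", "g10", "g11"],
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort for unit tests (3 datasets x 40 samples)."""
    return simulate_cohort(n_datasets=3, n_per_dataset=40, n_genes=4300, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the generator's default scale (5 datasets x 100)."""
    return simulate_cohort(seed=1)
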