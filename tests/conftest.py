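import numpy as np
import pandas as pd
import pytest

from consub import ExpressionMatrix, SyntheticCohortSpec, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0], [3.5, 4.25], [5.0, 0.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples x 400 genes, 3 planted subtypes, strong effect."""
    spec = SyntheticCohortSpec(
        n_samples=120, n_genes=400, k_subtypes=3, markers_per_subtype=40,
        effect=2.0, noise_sd=1.0, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def blocks_matrix():
    """Two perfectly separated correlation blocks of 6 samples each.

    Samples within a block are exact duplicates up to a tiny common scaling,
    so 1-Pearson distance is 0 within and ~2 between blocks.
    """
    rng = np.random.default_rng(5)
    base_a = rng.normal(0, 1, 30)
    base_b = -base_a
    cols = {}
    for i in range(6):
        cols[f"a{i}"] = base_a * (1 + 0.01 * i)
    for i in range(6):
        cols[f"b{i}"] = base_b * (1 + 0.01 * i)
    df = pd.DataFrame(cols, index=[f"g{j}" for j in range(30)])
    return ExpressionMatrix(df)
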