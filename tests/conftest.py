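import numpy as np
import pandas as pd
import pytest

from immsub import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SyntheticConfig,
    generate_bulk_dataset,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """5 genes x 2 samples with strictly decreasing expression in sample A."""
    data = pd.DataFrame(
        {"A": [5.0, 4.0, 3.0, 2.0, 1.0], "B": [1.0, 2.0, 3.0, 4.0, 5.0]},
        index=["G1", "G2", "G3", "G4", "G5"])
    return ExpressionMatrix(data, scale="linear")


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection.from_sets([
        GeneSet.from_genes("top", ["G1", "G2"]),
        GeneSet.from_genes("bottom", ["G4", "G5"]),
    ])


def random_matrix(rng: np.random.Generator, n_genes: int = 30,
                  n_samples: int = 5) -> ExpressionMatrix:
    data = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=1.0, size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)])
    return ExpressionMatrix(data, scale="linear")


@pytest.fixture(scope="session")
def bulk_seed1():
    """Default synthetic bulk cohort at n=150, shared across tests."""
    return generate_bulk_dataset(SyntheticConfig(seed=1, n_samples=150))


@pytest.fixture(scope="session")
def bulk_seed1_n300():
    return generate_bulk_dataset(SyntheticConfig(seed=1, n_samples=300))
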