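import numpy as np
import pandas as pd
import pytest

from rmnet import AbundanceMatrix, RMNParams, infer_network


@pytest.fixture
def toy_matrix() -> AbundanceMatrix:
    """Three-taxon, four-sample matrix with a hand-enumerable rule structure.

    X tracks Y (cooperator) and anti-tracks Z (competitor) over consecutive
    sample pairs.
    """
    df = pd.DataFrame(
        {
            "s1": [0.10, 0.10, 0.20],
            "s2": [0.30, 0.20, 0.05],
            "s3": [0.05, 0.05, 0.25],
            "s4": [0.33, 0.25, 0.10],
        },
        index=["X", "Y", "Z"],
    )
    return AbundanceMatrix(df)


@pytest.fixture
def toy_params() -> RMNParams:
    return RMNParams(epsilon=0.01, pair_mode="consecutive")


@pytest.fixture
def toy_network(toy_matrix, toy_params):
    return infer_network(toy_matrix, toy_params)


def random_abundance(seed: int, n_taxa: int = 5, n_samples: int = 6) -> AbundanceMatrix:
    """Random compositional matrix for property tests."""
    rng = np.random.default_rng(seed)
    raw = rng.gamma(1.0, 1.0, size=(n_taxa, n_samples)) + 1e-9
    frac = raw / raw.sum(axis=0)
    return AbundanceMatrix(
        pd.DataFrame(
            frac,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
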