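import numpy as np
import pandas as pd
import pytest

from projgwas import (
    SimulationParams,
    feature_gwas,
    partial_covariance,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared across tests: 400 samples,
    150 variants, 6 phenotypes, 3 covariates + intercept."""
    params = SimulationParams(
        n_samples=400, n_variants=150, n_phenotypes=6, n_covariates=3, seed=11
    )
    G, X, Z, truth = simulate_dataset(params)
    return G, X, Z, truth


@pytest.fixture(scope="session")
def small_stats(small_dataset):
    """Feature summary statistics and partial covariance for the shared
    dataset."""
    G, X, Z, _ = small_dataset
    return feature_gwas(G, X, Z), partial_covariance(X, Z)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def max_rel_err(a, b, floor=1e-300):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    assert ok.any()
    return float(np.max(np.abs(a[ok] - b[ok]) / np.maximum(np.abs(a[ok]), floor)))


@pytest.fixture(scope="session")
def rel_err():
    return max_rel_err
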