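import numpy as np
import pandas as pd
import pytest

import pdacmicro as pm


@pytest.fixture(scope="session")
def default_spec() -> pm.SyntheticSpec:
    """The reference study condition: 200 species, 60+60 samples, 15 species
    enriched 4-fold and 12 depleted to 0.25-fold, seed 42."""
    return pm.SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return pm.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def model_table(default_cohort):
    """Default cohort after the prevalence and model-abundance screens."""
    return pm.filter_model_features(pm.filter_taxa(default_cohort.profile))


@pytest.fixture(scope="session")
def case_labels(default_cohort) -> np.ndarray:
    return (default_cohort.metadata["group"] == "PDAC").to_numpy()


@pytest.fixture(scope="session")
def ensemble_m1(model_table, case_labels):
    """Unconstrained repeated-CV LASSO ensemble on the default cohort."""
    return pm.train_ensemble(model_table, case_labels, seed=1)


@pytest.fixture(scope="session")
def ensemble_m2(model_table, case_labels):
    """Enrichment-constrained ensemble on the default cohort."""
    return pm.train_ensemble(
        model_table, case_labels, variant="enrichment_constrained", seed=1
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def random_profile(rng, n_features=30, n_samples=12, sparsity=0.3) -> pd.DataFrame:
    """Small random relative-abundance table for oracle comparisons."""
    x = rng.lognormal(mean=-8, sigma=2, size=(n_features, n_samples))
    x[rng.random(x.shape) < sparsity] = 0.0
    x /= x.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        x,
        index=[f"sp{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
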