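import numpy as np
import pandas as pd
import pytest

import rpskit as rk


@pytest.fixture(scope="session")
def small_cohort():
    """A small labelled cohort with planted signal, shared across tests."""
    cfg = rk.SimulationConfig(
        n_genes=300, n_samples=60, n_de_genes=40, effect_size=1.0, seed=7
    )
    return rk.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_weights(small_cohort):
    expr, ann, _ = small_cohort
    stats = rk.fit_logistic_weights(expr, ann["response"])
    return rk.build_weight_profiles(stats)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        {"s1": [1.0, 4.0, 2.0], "s2": [2.0, 5.0, 8.0]},
        index=pd.Index(["a", "b", "c"], name="gene_id"),
    )
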