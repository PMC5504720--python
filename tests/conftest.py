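import logging

import numpy as np
import pandas as pd
import pytest

from mixewas import simulate_cohort

logging.getLogger("mixewas").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Small drifted cohort with planted age CpGs, shared across tests."""
    return simulate_cohort(
        n=40, m=300, K=2, drift=0.003, n_age_cpgs=20, slope=0.03, seed=11
    )


@pytest.fixture(scope="session")
def null_cohort():
    """No drift, no planted effects."""
    return simulate_cohort(n=30, m=200, K=2, drift=0.0, n_age_cpgs=0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_beta(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j:02d}" for j in range(values.shape[1])]
    from mixewas import BetaMatrix

    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))
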