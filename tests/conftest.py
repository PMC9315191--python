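import numpy as np
import pytest

from megh import (
    LogLogistic,
    NormalRandomEffects,
    PowerGeneralisedWeibull,
    fit_mmle,
    simulate_dataset,
    table1_design,
)
from megh.simulate import default_cluster_sizes


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down benchmark design: 8 clusters, n=160, normal RE sd=1."""
    return table1_design(structure="megh1", sigma_u=1.0).replace(
        cluster_sizes=default_cluster_sizes(160, 8)
    )


@pytest.fixture(scope="session")
def small_data(small_design):
    return simulate_dataset(small_design, seed=20260920)


@pytest.fixture(scope="session")
def small_fit(small_design, small_data):
    """MEGH-I fit of the small dataset (correct specification)."""
    return fit_mmle(
        small_data,
        structure="megh1",
        baseline="pgw",
        random_effects="normal",
        starts="gh",
    )


@pytest.fixture(scope="session")
def tiny_loglogistic_design():
    """Very small log-logistic design for oracle comparisons (4 clusters)."""
    return table1_design(
        structure="megh1", sigma_u=0.8, baseline=LogLogistic(0.5, 0.8)
    ).replace(cluster_sizes=default_cluster_sizes(48, 4))


@pytest.fixture(scope="session")
def tiny_data(tiny_loglogistic_design):
    return simulate_dataset(tiny_loglogistic_design, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(
    scope="session",
    params=[
        PowerGeneralisedWeibull(0.2, 1.5, 3.0),
        PowerGeneralisedWeibull(2.0, 0.7, 0.5),
        LogLogistic(0.0, 1.0),
        LogLogistic(0.5, 0.6),
    ],
    ids=["pgw-bench", "pgw-dec", "loglog-std", "loglog-peaked"],
)
def any_baseline(request):
    return request.param
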