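import numpy as np
import pandas as pd
import pytest

from funconn import (
    FisherZConnectivity,
    SimulationConfig,
    default_node_table,
    edgewise_comparison,
    generate_cohort,
)


@pytest.fixture(scope="session")
def node_table():
    return default_node_table()


@pytest.fixture(scope="session")
def small_cfg():
    """A 12-node, 18-subject cohort: fast enough for unit tests."""
    return SimulationConfig(
        n_nodes=12,
        n_controls=10,
        n_patients=8,
        t_samples=60,
        module_sizes=[6, 6],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def null_cohort_replicates():
    """Edge-wise inference on 200 full-scale null cohorts (no planted effect).

    Returns per-cohort (raw rejection rate at p < 0.05, number of BH
    discoveries at q < 0.05).  Shared across calibration tests because the
    simulation is the expensive part.
    """
    out = []
    for k in range(200):
        cohort, _ = generate_cohort(SimulationConfig(seed=100_000 + k))
        mats = FisherZConnectivity().fit_transform(cohort.series)
        res = edgewise_comparison(mats, cohort.covariates)
        out.append(((res["p"] < 0.05).mean(), int((res["q"] <= 0.05).sum())))
    return out


def random_signed_graph(rng: np.random.Generator, n: int, p_edge: float = 0.7) -> np.ndarray:
    """Random symmetric signed weighted graph with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(-1, 1)
    return w


def random_positive_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected non-negative weighted graph (spanning chain + extras)."""
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        w[a, b] = w[b, a] = rng.uniform(0.1, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w


@pytest.fixture(scope="session")
def demo_covariates():
    rng = np.random.default_rng(5)
    n = 107
    group = np.array([0] * 67 + [1] * 40)
    return pd.DataFrame(
        {
            "group": group,
            "age": rng.normal(23.3, 5.0, n),
            "sex": rng.integers(0, 2, n),
            "psychosis": group * rng.integers(0, 2, n),
            "mean_fd": rng.uniform(0.05, 0.3, n),
        }
    )
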