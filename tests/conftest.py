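import numpy as np
import pytest

from ssrtrace.extract import FeatureKey, FeatureMatrix, GroupLabels
from ssrtrace.simulate import SimulationConfig, simulate_feature_table


def make_matrix(values, groups, prefix="s"):
    """Small helper: binary array + per-row group names -> (matrix, labels)."""
    values = np.asarray(values)
    n, m = values.shape
    sample_ids = [f"{prefix}{i:02d}" for i in range(n)]
    keys = [FeatureKey(f"L{j:03d}", "AT", 5 + j % 3) for j in range(m)]
    labels = GroupLabels(dict(zip(sample_ids, groups)))
    return FeatureMatrix(sample_ids, keys, values), labels


def random_matrix(rng, n, m, n_groups):
    values = (rng.random((n, m)) < 0.5).astype(int)
    groups = [f"g{rng.integers(n_groups)}" for _ in range(n)]
    # ensure every group is realized
    for gi in range(n_groups):
        groups[gi % n] = f"g{gi}"
    return make_matrix(values, groups)


@pytest.fixture(scope="session")
def paper_shaped():
    """Default study-shaped synthetic table: 38 samples, 4 groups, PG heterogeneous."""
    cfg = SimulationConfig(seed=0)
    return simulate_feature_table(cfg)


@pytest.fixture(scope="session")
def separable_table():
    """Noise-free planted table: groups are perfectly separable."""
    cfg = SimulationConfig(
        group_names=("A", "B", "C"),
        samples_per_group=(5, 4, 6),
        n_conserved_per_group=(3, 3, 3),
        n_noise_features=0,
        noise_presence_prob=0.0,
        heterogeneous_groups=frozenset(),
        seed=5,
    )
    return simulate_feature_table(cfg)
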