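import numpy as np
import pytest
from hypothesis import settings

from bgmix import MixedDataset, SimConfig, TIGHT, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_dataset() -> MixedDataset:
    """Four entities, two binary and two continuous variables, split into
    two obvious groups."""
    return MixedDataset(
        entity_ids=["a", "b", "c", "d"],
        binary_names=["f1", "f2"],
        continuous_names=["e1", "e2"],
        R=np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float),
        E=np.array(
            [[1.0, 2.0], [1.2, 2.1], [-1.0, -2.0], [-1.1, -1.9]]
        ),
    )


@pytest.fixture
def tight_small():
    """Sixty tight-scenario points in six true clusters of ten."""
    cfg = SimConfig(n_points=60, cluster_size=10, scenario=TIGHT, seed=42)
    data, truth = simulate(cfg)
    return data, truth


def random_dataset(rng: np.random.Generator, n=8, n_r=3, n_e=2) -> MixedDataset:
    return MixedDataset(
        entity_ids=[f"x{i}" for i in range(n)],
        binary_names=[f"b{j}" for j in range(n_r)],
        continuous_names=[f"c{l}" for l in range(n_e)],
        R=rng.integers(0, 2, size=(n, n_r)).astype(float),
        E=rng.normal(size=(n, n_e)),
    )
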