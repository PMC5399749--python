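"""Synthetic mixed binary/continuous data with known cluster structure.

Two noise regimes are provided.  In the *tight* regime every Bernoulli
probability is 0.9 or 0.1 and every Gaussian standard deviation is 0.01,
giving well-separated clusters; the *noisy* regime uses 0.9 / 0.4 and
sigma = 0.3, giving overlapping clusters.  Clusters have exactly equal
sizes, each with a distinct randomly drawn pattern of Bernoulli
probabilities and Gaussian means (means uniform on ``mu_range``), and both
variable blocks default to 20 columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .model import ComponentParams, HardClustering, MixedDataset, MixtureModel

__all__ = [
    "SimScenario",
    "TIGHT",
    "NOISY",
    "SimConfig",
    "SimTruth",
    "make_true_model",
    "sample_dataset",
    "simulate",
    "adjusted_rand_index",
    "recovery_metrics",
]


@dataclass(frozen=True)
class SimScenario:
    name: str
    p_high: float = 0.9
    p_low: float = 0.1
    sigma: float = 0.01
    mu_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        expected = {"tight": (0.1, 0.01), "noisy": (0.4, 0.3)}
        if self.name not in expected:
            raise ValueError("scenario name must be 'tight' or 'noisy'")
        if (self.p_low, self.sigma) != expected[self.name]:
            raise ValueError(
                f"{self.name} scenario requires (p_low, sigma) = "
                f"{expected[self.name]}"
            )


TIGHT = SimScenario(name="tight", p_low=0.1, sigma=0.01)
NOISY = SimScenario(name="noisy", p_low=0.4, sigma=0.3)


@dataclass(frozen=True)
class SimConfig:
    n_points: int
    cluster_size: int
    n_r: int = 20
    n_e: int = 20
    scenario: SimScenario = TIGHT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points % self.cluster_size != 0:
            raise ValueError("n_points must be divisible by cluster_size")

    @property
    def n_clusters(self) -> int:
        return self.n_points // self.cluster_size


@dataclass
class SimTruth:
    labels: np.ndarray
    true_model: MixtureModel

    @property
    def n_clusters(self) -> int:
        return self.true_model.n_components

    def clustering(self) -> HardClustering:
        return HardClustering.from_labels(self.labels)


def make_true_model(config: SimConfig, rng: np.random.Generator | None = None
                    ) -> MixtureModel:
    """Draw the generating mixture: per cluster, each Bernoulli probability
    is p_high or p_low with probability 1/2, each Gaussian mean is uniform on
    ``mu_range`` and every sigma is the scenario's sigma.  Patterns are
    redrawn (bounded retries) until all clusters are pairwise distinct in
    their (p, rounded-mu) signature."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sc = config.scenario
    k = config.n_clusters
    alpha = config.cluster_size / config.n_points
    seen: set[tuple] = set()
    comps: list[ComponentParams] = []
    for _ in range(k):
        for attempt in range(1000):
            p = np.where(rng.random(config.n_r) < 0.5, sc.p_high, sc.p_low)
            mu = rng.uniform(*sc.mu_range, size=config.n_e)
            sig = tuple(p.tolist()) + tuple(np.round(mu, 6).tolist())
            if sig not in seen:
                seen.add(sig)
                break
        else:
            raise RuntimeError(
                "could not draw distinct cluster patterns; too few variables"
            )
        comps.append(
            ComponentParams(
                alpha=alpha, p=p, mu=mu,
                sigma=np.full(config.n_e, sc.sigma),
            )
        )
    return MixtureModel(components=comps, n_r=config.n_r, n_e=config.n_e)


def sample_dataset(
    model: MixtureModel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MixedDataset, SimTruth]:
    """Draw exactly ``cluster_size`` points from every component (stratified
    equal-size design, not multinomial)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_points
    labels = np.repeat(np.arange(model.n_components), config.cluster_size)
    R = np.zeros((n, config.n_r))
    E = np.zeros((n, config.n_e))
    for m, comp in enumerate(model.components):
        rows = slice(m * config.cluster_size, (m + 1) * config.cluster_size)
        size = (config.cluster_size, config.n_r)
        R[rows] = (rng.random(size) < comp.p).astype(float)
        E[rows] = rng.normal(
            comp.mu, comp.sigma, size=(config.cluster_size, config.n_e)
        )
    data = MixedDataset(
        entity_ids=[f"e{i:04d}" for i in range(n)],
        binary_names=[f"b{j:02d}" for j in range(config.n_r)],
        continuous_names=[f"c{l:02d}" for l in range(config.n_e)],
        R=R,
        E=E,
    )
    return data, SimTruth(labels=labels, true_model=model)


def simulate(config: SimConfig) -> tuple[MixedDataset, SimTruth]:
    """Model draw plus stratified sampling from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    model = make_true_model(config, rng)
    return sample_dataset(model, config, rng)


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected partition agreement from the pair-counting
    contingency table; 1 means identical up to relabelling."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)
    sum_cells = comb(ct, 2).sum()
    sum_rows = comb(ct.sum(axis=1), 2).sum()
    sum_cols = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def recovery_metrics(found: HardClustering, truth: SimTruth) -> dict:
    """Difference in cluster number and adjusted Rand index against the
    generating labels."""
    if found.n != truth.labels.size:
        raise ValueError("clustering and truth differ in length")
    return {
        "delta_k": found.n_clusters - truth.n_clusters,
        "ari": adjusted_rand_index(found.assignment, truth.labels),
    }
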