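"""Joint Bernoulli-Gaussian mixture model: containers, likelihoods and the
penalized model-selection objective.

Entities are described by ``n_r`` binary variables (e.g. transcription-factor
binding calls, mutation presence) and ``n_e`` continuous variables (e.g.
expression values across samples or time points).  Each mixture component m
has a mixing weight ``alpha_m``, an independent Bernoulli probability
``p_mj`` per binary variable and a diagonal Gaussian ``N(mu_ml, sigma_ml)``
per continuous variable.  Model selection minimizes the penalized objective

    O(L, k) = -2 L + k * lambda(N)

where ``L`` is a maximized log-likelihood, ``k`` the number of free
parameters and ``lambda(N)`` an information-criterion penalty (constant
lambda = 2 is the classical AIC; ln N the BIC; 2 ln ln N Hannan-Quinn;
1 + ln N the consistent AIC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "P_FLOOR",
    "SIGMA_FLOOR",
    "MixedDataset",
    "ComponentParams",
    "MixtureModel",
    "HardClustering",
    "PenaltySpec",
    "log_component_density",
    "log_likelihood_mixture",
    "fit_component_mle",
    "classification_log_likelihood",
    "count_parameters",
    "penalty_value",
    "objective",
]

#: Bernoulli probabilities are clamped to [P_FLOOR, 1 - P_FLOOR] so that a
#: pure cluster (all zeros or all ones in a column) keeps a finite
#: log-density.  Well below any realistic binding/mutation noise level.
P_FLOOR = 1e-3

#: Lower bound on every Gaussian standard deviation.  The classification
#: likelihood is unbounded as any cluster variance shrinks to zero, so a
#: singleton (or duplicate-point) cluster would otherwise dominate every
#: penalized objective; the floor caps that gain at -ln(SIGMA_FLOOR) per
#: variable.  The default equals the tightest noise scale the model is
#: expected to resolve (sigma = 0.01); with it, the per-parameter penalty
#: of an extra cluster outweighs the degenerate-variance gain for AIC-type
#: penalties, while genuine clusters at or above that scale are unaffected.
SIGMA_FLOOR = 0.01

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class MixedDataset:
    """N entities with an aligned binary block R (N x n_r) and continuous
    block E (N x n_e).  Either block may be empty (``n_r == 0`` gives
    expression-only clustering)."""

    entity_ids: list[str]
    binary_names: list[str]
    continuous_names: list[str]
    R: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.R.ndim != 2 or self.E.ndim != 2:
            raise ValueError("R and E must be 2-D matrices")
        n = len(self.entity_ids)
        if len(set(self.entity_ids)) != n:
            raise ValueError("entity_ids must be unique")
        if self.R.shape[0] != n:
            raise ValueError(
                f"binary block has {self.R.shape[0]} rows for {n} entities"
            )
        if self.E.shape[0] != n:
            raise ValueError(
                f"continuous block has {self.E.shape[0]} rows for {n} entities"
            )
        if self.R.shape[1] != len(self.binary_names):
            raise ValueError("binary_names length does not match R columns")
        if self.E.shape[1] != len(self.continuous_names):
            raise ValueError("continuous_names length does not match E columns")
        if n < 1:
            raise ValueError("dataset must contain at least one entity")
        if self.n_r + self.n_e < 1:
            raise ValueError("dataset needs at least one variable")
        if self.R.size and not np.isin(self.R, (0.0, 1.0)).all():
            raise ValueError("binary block contains entries other than 0/1")
        if self.E.size and not np.isfinite(self.E).all():
            raise ValueError("continuous block contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    @property
    def n_r(self) -> int:
        return self.R.shape[1]

    @property
    def n_e(self) -> int:
        return self.E.shape[1]


@dataclass
class ComponentParams:
    """Parameters of one mixture component."""

    alpha: float
    p: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0) or not np.isfinite(self.sigma).all():
            raise ValueError("sigma entries must be positive and finite")
        if self.p.size and (np.any(self.p <= 0) or np.any(self.p >= 1)):
            raise ValueError("p entries must lie strictly inside (0, 1)")

    @property
    def n_r(self) -> int:
        return self.p.shape[0]

    @property
    def n_e(self) -> int:
        return self.mu.shape[0]


@dataclass
class MixtureModel:
    """A finite mixture of Bernoulli-Gaussian components."""

    components: list[ComponentParams]
    n_r: int
    n_e: int

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("mixture needs at least one component")
        for c in self.components:
            if c.n_r != self.n_r or c.n_e != self.n_e:
                raise ValueError("component dimensions disagree with mixture")
        total = sum(c.alpha for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing weights sum to {total}, not 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([c.alpha for c in self.components])


@dataclass
class HardClustering:
    """Hard assignment of each entity to exactly one cluster.

    Cluster labels are 0-based and compact: every label in ``0..n_clusters-1``
    has at least one member.
    """

    assignment: np.ndarray
    n_clusters: int = field(default=0)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        labels = np.unique(self.assignment)
        k = labels.size
        if self.n_clusters == 0:
            self.n_clusters = k
        if not np.array_equal(labels, np.arange(self.n_clusters)):
            raise ValueError("cluster labels must be compact 0..k-1, all non-empty")

    @property
    def n(self) -> int:
        return self.assignment.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)

    @staticmethod
    def from_labels(labels: Sequence[int]) -> "HardClustering":
        """Build from arbitrary integer labels, compacting them in order of
        first appearance."""
        labels = np.asarray(labels, dtype=np.int64)
        # relabel in order of first appearance for stability
        order = {}
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in order:
                order[lab] = len(order)
            out[i] = order[lab]
        return HardClustering(assignment=out)


_PENALTY_KINDS = ("constant", "bic", "hannan_quinn", "caic")


@dataclass(frozen=True)
class PenaltySpec:
    """Which penalty multiplier lambda(N) is in force."""

    kind: str = "constant"
    lam: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _PENALTY_KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.kind == "constant" and not self.lam > 0:
            raise ValueError("constant penalty requires lam > 0")

    def describe(self) -> str:
        if self.kind == "constant":
            return f"constant lambda={self.lam:g}" + (
                " (AIC)" if self.lam == 2.0 else ""
            )
        return {"bic": "BIC ln N", "hannan_quinn": "Hannan-Quinn 2 ln ln N",
                "caic": "CAIC 1 + ln N"}[self.kind]


def penalty_value(spec: PenaltySpec, n: int) -> float:
    """Evaluate lambda(N) for the requested criterion."""
    if spec.kind == "constant":
        return float(spec.lam)
    if spec.kind == "bic":
        if n < 2:
            raise ValueError("BIC penalty requires N >= 2")
        return math.log(n)
    if spec.kind == "hannan_quinn":
        if n < 3:
            raise ValueError("Hannan-Quinn penalty requires N >= 3")
        return 2.0 * math.log(math.log(n))
    if spec.kind == "caic":
        if n < 2:
            raise ValueError("CAIC penalty requires N >= 2")
        return 1.0 + math.log(n)
    raise AssertionError(spec.kind)


def count_parameters(n_components: int, n_r: int, n_e: int) -> int:
    """Free-parameter count: (N_m - 1) mixing weights, one Bernoulli
    probability per binary variable per component, and a mean plus a standard
    deviation per continuous variable per component."""
    if n_components < 1:
        raise ValueError("need at least one component")
    return (n_components - 1) + n_components * n_r + 2 * n_components * n_e


def objective(loglik: float, k: int, spec: PenaltySpec, n: int) -> float:
    """Penalized objective O(L, k) = -2 L + k lambda(N); lower is better."""
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return -2.0 * loglik + k * penalty_value(spec, n)


def log_component_density(
    comp: ComponentParams, r: np.ndarray, e: np.ndarray
) -> float:
    """Log joint density of one data point under one component:
    sum_j [r_j ln p_j + (1-r_j) ln(1-p_j)] + sum_l ln N(e_l; mu_l, sigma_l).
    """
    r = np.asarray(r, dtype=float)
    e = np.asarray(e, dtype=float)
    if r.shape[0] != comp.n_r:
        raise ValueError(
            f"binary block mismatch: point has {r.shape[0]} variables, "
            f"component has {comp.n_r}"
        )
    if e.shape[0] != comp.n_e:
        raise ValueError(
            f"continuous block mismatch: point has {e.shape[0]} variables, "
            f"component has {comp.n_e}"
        )
    out = 0.0
    if comp.n_r:
        out += float(r @ np.log(comp.p) + (1.0 - r) @ np.log1p(-comp.p))
    if comp.n_e:
        z = (e - comp.mu) / comp.sigma
        out += float(-0.5 * (z @ z) - np.log(comp.sigma).sum()
                     - 0.5 * comp.n_e * _LOG_2PI)
    return out


def _log_density_matrix(model: MixtureModel, data: MixedDataset) -> np.ndarray:
    """N x N_m matrix of log component densities (no mixing weights)."""
    if data.n_r != model.n_r or data.n_e != model.n_e:
        raise ValueError("model and dataset dimensions disagree")
    n, k = data.n, model.n_components
    out = np.zeros((n, k))
    R, E = data.R, data.E
    for m, c in enumerate(model.components):
        if model.n_r:
            out[:, m] += R @ np.log(c.p) + (1.0 - R) @ np.log1p(-c.p)
        if model.n_e:
            z = (E - c.mu) / c.sigma
            out[:, m] += (
                -0.5 * (z * z).sum(axis=1)
                - np.log(c.sigma).sum()
                - 0.5 * model.n_e * _LOG_2PI
            )
    return out


def log_likelihood_mixture(model: MixtureModel, data: MixedDataset) -> float:
    """Full marginal mixture log-likelihood, computed with log-sum-exp."""
    ld = _log_density_matrix(model, data) + np.log(model.alphas)
    hi = ld.max(axis=1)
    return float((hi + np.log(np.exp(ld - hi[:, None]).sum(axis=1))).sum())


def fit_component_mle(
    data: MixedDataset,
    member_indices: Sequence[int],
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> ComponentParams:
    """Per-cluster maximum-likelihood estimates: clamped Bernoulli column
    means, Gaussian column means, and floored population (1/n) standard
    deviations.  ``alpha`` is left at 0 for the caller to fill (n_m / N)."""
    idx = np.asarray(member_indices, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("cannot fit a component to an empty member set")
    p = np.clip(data.R[idx].mean(axis=0), p_floor, 1.0 - p_floor) \
        if data.n_r else np.empty(0)
    if data.n_e:
        mu = data.E[idx].mean(axis=0)
        sigma = np.maximum(data.E[idx].std(axis=0, ddof=0), sigma_floor)
    else:
        mu = np.empty(0)
        sigma = np.empty(0)
    return ComponentParams(alpha=0.0, p=p, mu=mu, sigma=sigma)


def model_from_clustering(
    data: MixedDataset,
    clustering: HardClustering,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> MixtureModel:
    """Mixture model with hard per-cluster MLEs and alpha_m = n_m / N."""
    comps = []
    for m in range(clustering.n_clusters):
        idx = np.flatnonzero(clustering.assignment == m)
        c = fit_component_mle(data, idx, p_floor=p_floor,
                              sigma_floor=sigma_floor)
        c.alpha = idx.size / data.n
        comps.append(c)
    return MixtureModel(components=comps, n_r=data.n_r, n_e=data.n_e)


def classification_log_likelihood(
    data: MixedDataset,
    clustering: HardClustering,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> float:
    """Hard-assignment (classification) log-likelihood: with per-cluster MLE
    parameters and alpha_m = n_m / N, the sum over entities of
    ln alpha_{z_i} + log f_{z_i}(x_i).  Used as the maximized L inside the
    annealing search; it lower-bounds the marginal mixture log-likelihood of
    the same model."""
    if clustering.n != data.n:
        raise ValueError("clustering and dataset have different N")
    model = model_from_clustering(data, clustering)
    total = 0.0
    for m, comp in enumerate(model.components):
        idx = np.flatnonzero(clustering.assignment == m)
        sub_r = data.R[idx]
        sub_e = data.E[idx]
        n_m = idx.size
        total += n_m * math.log(comp.alpha)
        if data.n_r:
            total += float(
                (sub_r @ np.log(comp.p) + (1 - sub_r) @ np.log1p(-comp.p)).sum()
            )
        if data.n_e:
            z = (sub_e - comp.mu) / comp.sigma
            total += float(
                -0.5 * (z * z).sum()
                - n_m * np.log(comp.sigma).sum()
                - 0.5 * n_m * data.n_e * _LOG_2PI
            )
    return total
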