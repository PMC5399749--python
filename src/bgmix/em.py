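"""Expectation-maximization refinement under the full mixture likelihood.

The annealing search returns a hard partition; EM relaxes it to posterior
("responsibility") memberships and re-estimates parameters by weighted
maximum likelihood, monotonically increasing the marginal mixture
log-likelihood.  Components whose effective count collapses below
``epsilon_w`` are dropped, so the number of components can shrink but never
grow during refinement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    P_FLOOR,
    SIGMA_FLOOR,
    ComponentParams,
    HardClustering,
    MixedDataset,
    MixtureModel,
    _log_density_matrix,
    log_likelihood_mixture,
)

__all__ = [
    "ResponsibilityMatrix",
    "EMResult",
    "e_step",
    "m_step",
    "run_em",
    "posterior_assignments",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

#: components with fewer effective observations than this are dropped
EPSILON_W = 1e-6


@dataclass
class ResponsibilityMatrix:
    """N x N_m posterior membership probabilities; rows sum to 1."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 2:
            raise ValueError("gamma must be 2-D")
        if np.any(self.gamma < -1e-12) or np.any(self.gamma > 1 + 1e-12):
            raise ValueError("gamma entries must lie in [0, 1]")
        rows = self.gamma.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("gamma rows must sum to 1")

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_components(self) -> int:
        return self.gamma.shape[1]


@dataclass
class EMResult:
    model: MixtureModel
    gamma: ResponsibilityMatrix
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def e_step(model: MixtureModel, data: MixedDataset) -> ResponsibilityMatrix:
    """Posterior membership probabilities, computed in log space."""
    ld = _log_density_matrix(model, data) + np.log(model.alphas)
    hi = ld.max(axis=1, keepdims=True)
    w = np.exp(ld - hi)
    gamma = w / w.sum(axis=1, keepdims=True)
    return ResponsibilityMatrix(gamma=gamma)


def m_step(
    data: MixedDataset,
    gamma: ResponsibilityMatrix,
    epsilon_w: float = EPSILON_W,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> MixtureModel:
    """Weighted maximum-likelihood updates.  Components with effective count
    below ``epsilon_w`` are dropped (with a warning) and weights
    renormalized."""
    g = gamma.gamma
    if g.shape[0] != data.n:
        raise ValueError("gamma and dataset have different N")
    counts = g.sum(axis=0)
    keep = np.flatnonzero(counts >= epsilon_w)
    if keep.size < g.shape[1]:
        logger.warning(
            "dropping %d empty component(s) with effective count < %g",
            g.shape[1] - keep.size, epsilon_w,
        )
        g = g[:, keep]
        counts = counts[keep]
    comps = []
    for m in range(g.shape[1]):
        w = g[:, m]
        nm = counts[m]
        if data.n_r:
            p = np.clip((w @ data.R) / nm, p_floor, 1.0 - p_floor)
        else:
            p = np.empty(0)
        if data.n_e:
            mu = (w @ data.E) / nm
            var = (w @ (data.E - mu) ** 2) / nm
            sigma = np.maximum(np.sqrt(np.maximum(var, 0.0)), sigma_floor)
        else:
            mu = np.empty(0)
            sigma = np.empty(0)
        comps.append(
            ComponentParams(alpha=float(nm / counts.sum()), p=p, mu=mu,
                            sigma=sigma)
        )
    return MixtureModel(components=comps, n_r=data.n_r, n_e=data.n_e)


def run_em(
    init: MixtureModel,
    data: MixedDataset,
    tol: float = 1e-6,
    max_iter: int = 500,
    epsilon_w: float = EPSILON_W,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> EMResult:
    """Alternate E and M steps from ``init`` until the absolute change in
    log-likelihood falls below ``tol`` or ``max_iter`` is reached.

    The log-likelihood trace is non-decreasing; a decrease beyond 1e-8 is an
    internal error (it would indicate a defective update, not data trouble).
    """
    model = init
    loglik = log_likelihood_mixture(model, data)
    trace = [loglik]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gamma = e_step(model, data)
        model = m_step(data, gamma, epsilon_w=epsilon_w,
                       p_floor=p_floor, sigma_floor=sigma_floor)
        new_loglik = log_likelihood_mixture(model, data)
        if new_loglik < loglik - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{loglik:.10g} -> {new_loglik:.10g}"
            )
        delta = new_loglik - loglik
        loglik = new_loglik
        trace.append(loglik)
        if abs(delta) < tol:
            converged = True
            break
    gamma = e_step(model, data)
    return EMResult(
        model=model, gamma=gamma, loglik_trace=trace,
        converged=converged, n_iter=it,
    )


def posterior_assignments(gamma: ResponsibilityMatrix) -> HardClustering:
    """Hard assignment to the highest-responsibility component, ties broken
    toward the lowest component index; empty components compacted."""
    labels = np.argmax(gamma.gamma, axis=1)
    return HardClustering.from_labels(labels)
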