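"""Post-processing of a fitted clustering: "clear" cluster extraction and
regulatory-network edge export.

A cluster is *clear* when its members' continuous profiles are mutually
consistent (average pairwise Pearson correlation strictly above
``r_threshold``) and at least one binary variable has within-cluster
probability strictly above ``b_threshold``.  Clear clusters are the units
reported as regulatory hypotheses; each (factor, clear cluster) pair with
probability above ``b_threshold`` becomes one network edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import HardClustering, MixedDataset, MixtureModel

__all__ = ["ClusterReport", "NetworkEdge", "clear_clusters", "network_edges"]


@dataclass
class ClusterReport:
    cluster_id: int
    size: int
    member_ids: list[str]
    avg_pairwise_expression_correlation: float
    max_binding_probability: float
    high_prob_factors: list[str] = field(default_factory=list)
    is_clear: bool = False


@dataclass
class NetworkEdge:
    factor: str
    cluster_id: int
    binding_probability: float
    annotation: str = ""


def _avg_pairwise_correlation(E: np.ndarray) -> float:
    if E.shape[0] < 2 or E.shape[1] < 2:
        return float("nan")
    sd = E.std(axis=1)
    if np.any(sd == 0):
        return float("nan")
    corr = np.corrcoef(E)
    iu = np.triu_indices(E.shape[0], k=1)
    return float(corr[iu].mean())


def clear_clusters(
    model: MixtureModel,
    clustering: HardClustering,
    data: MixedDataset,
    r_threshold: float = 0.5,
    b_threshold: float = 0.5,
) -> list[ClusterReport]:
    """Per-cluster report with the clear-cluster flag.  Singletons are never
    clear (their pairwise correlation is undefined); with no binary block the
    binding probability is NaN and no cluster can be clear."""
    if clustering.n != data.n:
        raise ValueError("clustering and dataset have different N")
    if model.n_components != clustering.n_clusters:
        raise ValueError("model and clustering disagree on cluster number")
    reports = []
    for m in range(clustering.n_clusters):
        idx = np.flatnonzero(clustering.assignment == m)
        comp = model.components[m]
        avg_corr = _avg_pairwise_correlation(data.E[idx]) if data.n_e else float("nan")
        if data.n_r:
            max_p = float(comp.p.max())
            high = [
                data.binary_names[j]
                for j in np.flatnonzero(comp.p > b_threshold)
            ]
        else:
            max_p = float("nan")
            high = []
        clear = (
            idx.size >= 2
            and not math.isnan(avg_corr)
            and avg_corr > r_threshold
            and not math.isnan(max_p)
            and max_p > b_threshold
        )
        reports.append(
            ClusterReport(
                cluster_id=m + 1,
                size=int(idx.size),
                member_ids=[data.entity_ids[i] for i in idx],
                avg_pairwise_expression_correlation=avg_corr,
                max_binding_probability=max_p,
                high_prob_factors=high,
                is_clear=clear,
            )
        )
    return reports


def network_edges(
    reports: list[ClusterReport],
    model: MixtureModel,
    binary_names: list[str],
    b_threshold: float = 0.5,
) -> list[NetworkEdge]:
    """One edge per (factor, clear cluster) pair with binding probability
    strictly above ``b_threshold``."""
    edges = []
    for rep in reports:
        if not rep.is_clear:
            continue
        comp = model.components[rep.cluster_id - 1]
        for j in np.flatnonzero(comp.p > b_threshold):
            edges.append(
                NetworkEdge(
                    factor=binary_names[j],
                    cluster_id=rep.cluster_id,
                    binding_probability=float(comp.p[j]),
                )
            )
    return edges


def reports_to_frame(reports: list[ClusterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "size": r.size,
                "member_ids": ",".join(r.member_ids),
                "avg_pairwise_expression_correlation":
                    r.avg_pairwise_expression_correlation,
                "max_binding_probability": r.max_binding_probability,
                "high_prob_factors": ",".join(r.high_prob_factors),
                "is_clear": r.is_clear,
            }
            for r in reports
        ]
    )


def edges_to_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": e.factor,
                "target": f"cluster_{e.cluster_id}",
                "weight": e.binding_probability,
            }
            for e in edges
        ],
        columns=["source", "target", "weight"],
    )
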