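"""Data-preparation steps for the two application domains.

For regulatory data: binarize a binding p-value matrix (bound iff
p < 0.001), z-score each entity's expression row, preselect binary factors
whose bound gene sets are enriched for highly correlated expression pairs
(empirical p against random same-size gene sets, generous threshold 0.1),
and drop entities bound by none of the retained factors.

For tumour-sample data: keep mutations recurring in at least two samples,
drop samples left without any mutation, and select the most variable
expression features by combined rank of coefficient of variation and
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "FactorRecord",
    "PreselectionReport",
    "binarize_binding",
    "normalize_expression",
    "preselect_binary_variables",
    "drop_unbound_entities",
    "filter_mutations",
    "select_variable_features",
]


@dataclass
class FactorRecord:
    factor: str
    n_bound: int
    observed_proportion: float
    empirical_p: float
    retained: bool


@dataclass
class PreselectionReport:
    rho: float
    records: list[FactorRecord] = field(default_factory=list)

    @property
    def retained_factors(self) -> list[str]:
        return [r.factor for r in self.records if r.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "factor": r.factor,
                    "n_bound": r.n_bound,
                    "observed_proportion": r.observed_proportion,
                    "empirical_p": r.empirical_p,
                    "retained": r.retained,
                }
                for r in self.records
            ]
        )


def binarize_binding(P: np.ndarray, threshold: float = 0.001) -> np.ndarray:
    """Binding call matrix: 1 iff p-value strictly below ``threshold``."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return (P < threshold).astype(float)


def normalize_expression(E: np.ndarray,
                         entity_ids: list[str] | None = None) -> np.ndarray:
    """Scale each row to zero mean and unit sample (n-1) standard
    deviation."""
    E = np.asarray(E, dtype=float)
    mean = E.mean(axis=1, keepdims=True)
    sd = E.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        name = entity_ids[flat[0]] if entity_ids else f"row {flat[0]}"
        raise ValueError(f"cannot normalize constant expression row: {name}")
    return (E - mean) / sd


def _pair_proportion(corr: np.ndarray, members: np.ndarray, rho: float) -> float:
    sub = corr[np.ix_(members, members)]
    iu = np.triu_indices(members.size, k=1)
    vals = sub[iu]
    return float((vals > rho).mean())


def preselect_binary_variables(
    R: np.ndarray,
    E: np.ndarray,
    factor_names: list[str],
    percentile: float = 95.0,
    n_random: int = 1000,
    p_threshold: float = 0.1,
    seed: int = 0,
) -> PreselectionReport:
    """Retain factors whose bound entities show more highly correlated
    expression pairs than random same-size entity sets.

    ``rho`` is the requested percentile of Pearson correlations over all
    entity pairs.  A factor's observed proportion is the fraction of pairs
    within its bound set with correlation strictly above ``rho``; its
    empirical p is the add-one-smoothed fraction of ``n_random`` random
    same-size sets whose proportion is at least the observed one.  Factors
    bound by fewer than two entities are auto-rejected.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    R = np.asarray(R, dtype=float)
    E = np.asarray(E, dtype=float)
    n = R.shape[0]
    if E.shape[0] != n or R.shape[1] != len(factor_names):
        raise ValueError("matrix shapes disagree with labels")
    corr = np.corrcoef(E)
    iu = np.triu_indices(n, k=1)
    rho = float(np.percentile(corr[iu], percentile))
    rng = np.random.default_rng(seed)
    records = []
    for j, name in enumerate(factor_names):
        bound = np.flatnonzero(R[:, j] == 1)
        if bound.size < 2:
            records.append(
                FactorRecord(
                    factor=name, n_bound=int(bound.size),
                    observed_proportion=float("nan"),
                    empirical_p=1.0, retained=False,
                )
            )
            continue
        observed = _pair_proportion(corr, bound, rho)
        hits = 0
        for _ in range(n_random):
            rand_set = rng.choice(n, size=bound.size, replace=False)
            if _pair_proportion(corr, rand_set, rho) >= observed:
                hits += 1
        emp_p = (1 + hits) / (1 + n_random)
        records.append(
            FactorRecord(
                factor=name, n_bound=int(bound.size),
                observed_proportion=observed, empirical_p=emp_p,
                retained=emp_p < p_threshold,
            )
        )
    return PreselectionReport(rho=rho, records=records)


def drop_unbound_entities(
    R: np.ndarray, E: np.ndarray, entity_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep only rows with at least one 1 among the (already subset) binary
    columns.  Returns (R', E', kept row indices)."""
    R = np.asarray(R, dtype=float)
    E = np.asarray(E, dtype=float)
    if E.shape[0] != R.shape[0]:
        raise ValueError("R and E are not row-aligned")
    keep = np.flatnonzero(R.sum(axis=1) >= 1)
    if keep.size == 0:
        raise ValueError("no entity is bound by any retained factor")
    return R[keep], E[keep], keep


def filter_mutations(
    M: np.ndarray, min_recurrence: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop mutation columns seen in fewer than ``min_recurrence`` samples,
    then drop samples whose remaining row is all zero (in that order).
    Returns (M', kept column indices, kept row indices)."""
    M = np.asarray(M, dtype=float)
    cols = np.flatnonzero(M.sum(axis=0) >= min_recurrence)
    if cols.size == 0:
        raise ValueError("no mutation meets the recurrence threshold")
    sub = M[:, cols]
    rows = np.flatnonzero(sub.sum(axis=1) > 0)
    if rows.size == 0:
        raise ValueError("no sample carries a retained mutation")
    return sub[rows], cols, rows


def select_variable_features(
    E: np.ndarray, k: int = 500, feature_names: list[str] | None = None
) -> np.ndarray:
    """Top-``k`` features (columns) by the mean of two ranks: rank of
    |coefficient of variation| and rank of standard deviation (higher rank =
    more variable).  Features with near-zero mean get the maximum CV rank
    (their CV is unstable but they are certainly variable).  Ties break by
    SD rank, then by column order.  Returns kept column indices."""
    E = np.asarray(E, dtype=float)
    n_feat = E.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds the {n_feat} available features")
    sd = E.std(axis=0, ddof=1)
    mean = E.mean(axis=0)
    guarded = np.abs(mean) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.abs(sd / mean)
    sd_rank = rankdata(sd, method="average")
    cv_rank = rankdata(np.where(guarded, np.inf, cv), method="average")
    cv_rank[guarded] = n_feat
    score = 0.5 * (sd_rank + cv_rank)
    order = np.lexsort((np.arange(n_feat), -sd_rank, -score))
    return np.sort(order[:k])
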