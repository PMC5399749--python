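"""Monte-Carlo simulated-annealing search over hard partitions.

The search state is a hard clustering of the N entities; the number of
clusters is free to change through the move set.  Each candidate is scored
with the penalized classification objective

    O = -2 * classification_log_likelihood + k(N_m) * lambda(N)

and accepted by the Metropolis rule at the current temperature.  Per-cluster
sufficient statistics (member counts, binary column sums, continuous sums
and sums of squares) make every move evaluable in O(n_r + n_e) per touched
cluster, so the full objective is never recomputed in the hot loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    P_FLOOR,
    SIGMA_FLOOR,
    HardClustering,
    MixedDataset,
    MixtureModel,
    PenaltySpec,
    classification_log_likelihood,
    count_parameters,
    model_from_clustering,
    objective,
    penalty_value,
)

__all__ = [
    "AnnealSchedule",
    "SearchResult",
    "ObjectiveCache",
    "initialize_clustering",
    "propose_move",
    "anneal",
    "anneal_restarts",
]

_LOG_2PI = math.log(2.0 * math.pi)

MOVES = ("REASSIGN", "SPLIT", "MERGE", "NEW")


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule.

    ``moves_per_temperature`` is a multiplier on N (the default
    visits each entity many times per level); ``max_no_improve`` stops the
    run after that many consecutive temperature levels without improving the
    best objective.
    """

    t_init: float = 10.0
    t_final: float = 0.01
    cooling: float = 0.95
    moves_per_temperature: int = 50
    max_no_improve: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_init > 0 and self.t_final > 0):
            raise ValueError("temperatures must be positive")
        if self.t_final > self.t_init:
            raise ValueError("t_final must not exceed t_init")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.moves_per_temperature < 1 or self.max_no_improve < 1:
            raise ValueError("schedule counts must be >= 1")


@dataclass
class SearchResult:
    best_clustering: HardClustering
    best_model: MixtureModel
    best_objective: float
    best_loglik: float
    trace: list[tuple[float, float, float, int]] = field(default_factory=list)


class ObjectiveCache:
    """Per-cluster sufficient statistics and scores for the hard-assignment
    objective.

    Cluster slots live in fixed-capacity arrays; freed slots are recycled.
    ``score[c]`` holds the cluster's full contribution to the classification
    log-likelihood, including its ``n_m ln(n_m/N)`` mixing term, so the total
    objective is ``-2 * sum(score over active) + k(N_m) * lambda(N)``.
    """

    def __init__(self, data: MixedDataset, assignment: np.ndarray,
                 spec: PenaltySpec, p_floor: float = P_FLOOR,
                 sigma_floor: float = SIGMA_FLOOR):
        self.data = data
        self.p_floor = p_floor
        self.sigma_floor = sigma_floor
        self.n = data.n
        self.n_r = data.n_r
        self.n_e = data.n_e
        self.lam = penalty_value(spec, data.n)
        # objective cost of one extra component under the counting convention
        self.k_per_cluster = 1 + self.n_r + 2 * self.n_e
        cap = self.n + 1
        self.counts = np.zeros(cap, dtype=np.int64)
        self.rsum = np.zeros((cap, self.n_r))
        self.esum = np.zeros((cap, self.n_e))
        self.e2sum = np.zeros((cap, self.n_e))
        self.score = np.zeros(cap)
        self.active: set[int] = set()
        self.free: list[int] = list(range(cap - 1, -1, -1))
        self.assignment = np.asarray(assignment, dtype=np.int64).copy()
        self._E2 = data.E * data.E
        relabel = {}
        for i, lab in enumerate(self.assignment):
            if lab not in relabel:
                relabel[lab] = self._new_cluster()
            self.assignment[i] = relabel[lab]
        for c in self.active:
            idx = np.flatnonzero(self.assignment == c)
            self.counts[c] = idx.size
            if self.n_r:
                self.rsum[c] = data.R[idx].sum(axis=0)
            if self.n_e:
                self.esum[c] = data.E[idx].sum(axis=0)
                self.e2sum[c] = self._E2[idx].sum(axis=0)
            self.score[c] = self._cluster_score(c)

    # -- slot management -------------------------------------------------
    def _new_cluster(self) -> int:
        c = self.free.pop()
        self.active.add(c)
        self.counts[c] = 0
        if self.n_r:
            self.rsum[c] = 0.0
        if self.n_e:
            self.esum[c] = 0.0
            self.e2sum[c] = 0.0
        self.score[c] = 0.0
        return c

    def _drop_cluster(self, c: int) -> None:
        self.active.remove(c)
        self.free.append(c)
        self.score[c] = 0.0
        self.counts[c] = 0

    # -- scoring ---------------------------------------------------------
    def _score_from_stats(self, n: int, rsum, esum, e2sum) -> float:
        """Classification log-likelihood contribution of one cluster with
        clamped/floored MLE parameters, plus its n ln(n/N) mixing term."""
        s = n * (math.log(n) - math.log(self.n))
        if self.n_r:
            p = np.clip(rsum / n, self.p_floor, 1.0 - self.p_floor)
            s += float(rsum @ np.log(p) + (n - rsum) @ np.log1p(-p))
        if self.n_e:
            mu = esum / n
            ssd = np.maximum(e2sum - esum * mu, 0.0)
            sd = np.maximum(np.sqrt(ssd / n), self.sigma_floor)
            s += float(
                -np.log(sd).sum() * n
                - (ssd / (2.0 * sd * sd)).sum()
                - 0.5 * n * self.n_e * _LOG_2PI
            )
        return s

    def _cluster_score(self, c: int) -> float:
        return self._score_from_stats(
            int(self.counts[c]), self.rsum[c], self.esum[c], self.e2sum[c]
        )

    @property
    def n_clusters(self) -> int:
        return len(self.active)

    def total_objective(self) -> float:
        k = count_parameters(self.n_clusters, self.n_r, self.n_e)
        return -2.0 * float(self.score[list(self.active)].sum()) + k * self.lam

    # -- move evaluation (delta objective) --------------------------------
    # Each eval_* returns (delta_objective, payload); commit(payload) applies
    # the move.  Payloads carry the recomputed cluster scores so commit
    # never rescores anything.

    def eval_reassign(self, i: int, dst: int):
        src = self.assignment[i]
        if dst == src:
            return 0.0, None
        r = self.data.R[i] if self.n_r else None
        e = self.data.E[i] if self.n_e else None
        e2 = self._E2[i] if self.n_e else None
        n_src = int(self.counts[src])
        dk = 0.0
        if n_src == 1:
            new_src_score = 0.0
            dk = -self.k_per_cluster
        else:
            new_src_score = self._score_from_stats(
                n_src - 1,
                self.rsum[src] - r if self.n_r else None,
                self.esum[src] - e if self.n_e else None,
                self.e2sum[src] - e2 if self.n_e else None,
            )
        new_dst_score = self._score_from_stats(
            int(self.counts[dst]) + 1,
            self.rsum[dst] + r if self.n_r else None,
            self.esum[dst] + e if self.n_e else None,
            self.e2sum[dst] + e2 if self.n_e else None,
        )
        d_log = (new_src_score - self.score[src]) + (new_dst_score - self.score[dst])
        d_obj = -2.0 * d_log + dk * self.lam
        return d_obj, ("R", i, src, dst, new_src_score, new_dst_score)

    def eval_new(self, i: int):
        """Move entity i into a brand-new singleton cluster."""
        src = self.assignment[i]
        if self.counts[src] == 1:
            return 0.0, None  # already a singleton: no-op
        r = self.data.R[i] if self.n_r else None
        e = self.data.E[i] if self.n_e else None
        e2 = self._E2[i] if self.n_e else None
        new_src_score = self._score_from_stats(
            int(self.counts[src]) - 1,
            self.rsum[src] - r if self.n_r else None,
            self.esum[src] - e if self.n_e else None,
            self.e2sum[src] - e2 if self.n_e else None,
        )
        singleton_score = self._score_from_stats(1, r, e, e2)
        d_log = (new_src_score - self.score[src]) + singleton_score
        d_obj = -2.0 * d_log + self.k_per_cluster * self.lam
        return d_obj, ("N", i, src, new_src_score, singleton_score)

    def eval_merge(self, a: int, b: int):
        merged = self._score_from_stats(
            int(self.counts[a] + self.counts[b]),
            self.rsum[a] + self.rsum[b] if self.n_r else None,
            self.esum[a] + self.esum[b] if self.n_e else None,
            self.e2sum[a] + self.e2sum[b] if self.n_e else None,
        )
        d_log = merged - self.score[a] - self.score[b]
        d_obj = -2.0 * d_log - self.k_per_cluster * self.lam
        return d_obj, ("M", a, b, merged)

    def eval_split(self, c: int, members_a: np.ndarray, members_b: np.ndarray):
        stats = []
        for part in (members_a, members_b):
            n = part.size
            rs = self.data.R[part].sum(axis=0) if self.n_r else None
            es = self.data.E[part].sum(axis=0) if self.n_e else None
            e2s = self._E2[part].sum(axis=0) if self.n_e else None
            stats.append((n, rs, es, e2s, self._score_from_stats(n, rs, es, e2s)))
        d_log = stats[0][4] + stats[1][4] - self.score[c]
        d_obj = -2.0 * d_log + self.k_per_cluster * self.lam
        return d_obj, ("S", c, members_a, members_b, stats)

    # -- commit -----------------------------------------------------------
    def commit(self, payload) -> None:
        if payload is None:
            return
        tag = payload[0]
        if tag == "R":
            _, i, src, dst, s_src, s_dst = payload
            self._move_point_stats(i, src, dst)
            self.assignment[i] = dst
            if self.counts[src] == 0:
                self._drop_cluster(src)
            else:
                self.score[src] = s_src
            self.score[dst] = s_dst
        elif tag == "N":
            _, i, src, s_src, s_new = payload
            c = self._new_cluster()
            self._move_point_stats(i, src, c)
            self.assignment[i] = c
            self.score[src] = s_src
            self.score[c] = s_new
        elif tag == "M":
            _, a, b, merged = payload
            self.counts[a] += self.counts[b]
            if self.n_r:
                self.rsum[a] += self.rsum[b]
            if self.n_e:
                self.esum[a] += self.esum[b]
                self.e2sum[a] += self.e2sum[b]
            self.assignment[self.assignment == b] = a
            self.score[a] = merged
            self._drop_cluster(b)
        elif tag == "S":
            _, c, members_a, members_b, stats = payload
            nb = self._new_cluster()
            (na_n, na_rs, na_es, na_e2, na_sc) = stats[0]
            (nb_n, nb_rs, nb_es, nb_e2, nb_sc) = stats[1]
            self.counts[c] = na_n
            self.counts[nb] = nb_n
            if self.n_r:
                self.rsum[c] = na_rs
                self.rsum[nb] = nb_rs
            if self.n_e:
                self.esum[c] = na_es
                self.e2sum[c] = na_e2
                self.esum[nb] = nb_es
                self.e2sum[nb] = nb_e2
            self.assignment[members_b] = nb
            self.score[c] = na_sc
            self.score[nb] = nb_sc
        else:  # pragma: no cover
            raise AssertionError(tag)

    def _move_point_stats(self, i: int, src: int, dst: int) -> None:
        self.counts[src] -= 1
        self.counts[dst] += 1
        if self.n_r:
            r = self.data.R[i]
            self.rsum[src] -= r
            self.rsum[dst] += r
        if self.n_e:
            e = self.data.E[i]
            e2 = self._E2[i]
            self.esum[src] -= e
            self.e2sum[src] -= e2
            self.esum[dst] += e
            self.e2sum[dst] += e2

    # -- auditing ---------------------------------------------------------
    def audit(self, atol: float = 1e-6) -> None:
        """Debug check: cached stats and scores agree with a from-scratch
        rebuild.  Raises RuntimeError on inconsistency."""
        rebuilt = ObjectiveCache(
            self.data, self.assignment,
            PenaltySpec("constant", self.lam),
            p_floor=self.p_floor, sigma_floor=self.sigma_floor,
        )
        if rebuilt.n_clusters != self.n_clusters:
            raise RuntimeError("cache audit failed: cluster count mismatch")
        if abs(rebuilt.total_objective() - self.total_objective()) > atol:
            raise RuntimeError("cache audit failed: objective drift")

    def clustering(self) -> HardClustering:
        return HardClustering.from_labels(self.assignment)


def initialize_clustering(
    data: MixedDataset, k_init: int, seed: int | np.random.Generator
) -> HardClustering:
    """Uniform random assignment of entities to ``k_init`` clusters (empty
    clusters compacted, so the result may have fewer)."""
    if not 1 <= k_init <= data.n:
        raise ValueError(f"k_init must be in 1..{data.n}")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    labels = rng.integers(0, k_init, size=data.n)
    return HardClustering.from_labels(labels)


def propose_move(
    clustering: HardClustering, data: MixedDataset, rng: np.random.Generator
) -> tuple[HardClustering, str]:
    """Draw one move (REASSIGN / SPLIT / MERGE / NEW, equal probabilities;
    inapplicable kinds resampled) and return the candidate clustering.  The
    incumbent is never mutated.  A state admitting no move (single singleton
    cluster) returns the incumbent unchanged with label NOOP."""
    n, k = clustering.n, clustering.n_clusters
    labels = clustering.assignment
    sizes = clustering.sizes()
    applicable = []
    if k >= 2:
        applicable += ["REASSIGN", "MERGE"]
    if (sizes >= 2).any():
        applicable += ["SPLIT", "NEW"]
    if not applicable:
        return clustering, "NOOP"
    move = applicable[rng.integers(len(applicable))]
    new = labels.copy()
    if move == "REASSIGN":
        i = rng.integers(n)
        choices = [c for c in range(k) if c != labels[i]]
        new[i] = choices[rng.integers(len(choices))]
    elif move == "MERGE":
        a, b = rng.choice(k, size=2, replace=False)
        new[new == b] = a
    elif move == "NEW":
        big = np.flatnonzero(sizes[labels] >= 2)
        i = big[rng.integers(big.size)]
        new[i] = k
    else:  # SPLIT
        splittable = np.flatnonzero(sizes >= 2)
        c = splittable[rng.integers(splittable.size)]
        members = np.flatnonzero(labels == c)
        while True:
            mask = rng.integers(0, 2, size=members.size).astype(bool)
            if 0 < mask.sum() < members.size:
                break
        new[members[mask]] = k
    return HardClustering.from_labels(new), move


def _anneal_single(
    data: MixedDataset,
    spec: PenaltySpec,
    schedule: AnnealSchedule,
    k_init: int,
    rng: np.random.Generator,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> SearchResult:
    init = initialize_clustering(data, k_init, rng)
    cache = ObjectiveCache(data, init.assignment, spec,
                           p_floor=p_floor, sigma_floor=sigma_floor)
    current = cache.total_objective()
    best = current
    best_assign = cache.assignment.copy()
    trace: list[tuple[float, float, float, int]] = []
    t = schedule.t_init
    no_improve = 0
    moves_per_level = schedule.moves_per_temperature * data.n
    n = data.n
    while True:
        improved = False
        for _ in range(moves_per_level):
            kind = MOVES[rng.integers(4)]
            d_obj = 0.0
            payload = None
            if kind == "REASSIGN":
                if cache.n_clusters >= 2:
                    i = int(rng.integers(n))
                    act = tuple(cache.active)
                    dst = act[rng.integers(len(act))]
                    if dst != cache.assignment[i]:
                        d_obj, payload = cache.eval_reassign(i, dst)
            elif kind == "MERGE":
                if cache.n_clusters >= 2:
                    act = tuple(cache.active)
                    ia, ib = rng.choice(len(act), size=2, replace=False)
                    d_obj, payload = cache.eval_merge(act[ia], act[ib])
            elif kind == "NEW":
                i = int(rng.integers(n))
                if cache.counts[cache.assignment[i]] >= 2:
                    d_obj, payload = cache.eval_new(i)
            else:  # SPLIT
                act = tuple(cache.active)
                c = act[rng.integers(len(act))]
                if cache.counts[c] >= 2:
                    members = np.flatnonzero(cache.assignment == c)
                    mask = rng.integers(0, 2, size=members.size).astype(bool)
                    if 0 < mask.sum() < members.size:
                        d_obj, payload = cache.eval_split(
                            c, members[~mask], members[mask]
                        )
            if payload is None:
                continue
            if d_obj <= 0.0 or rng.random() < math.exp(-d_obj / t):
                cache.commit(payload)
                current += d_obj
                if current < best - 1e-9:
                    best = current
                    best_assign = cache.assignment.copy()
                    improved = True
        # resync the running objective against the cached cluster scores to
        # stop float drift accumulating over many levels
        current = cache.total_objective()
        if current < best - 1e-9:
            best = current
            best_assign = cache.assignment.copy()
            improved = True
        trace.append((t, current, best, cache.n_clusters))
        no_improve = 0 if improved else no_improve + 1
        if t <= schedule.t_final or no_improve >= schedule.max_no_improve:
            break
        t *= schedule.cooling
    best_clustering = HardClustering.from_labels(best_assign)
    best_model = model_from_clustering(data, best_clustering,
                                       p_floor=p_floor,
                                       sigma_floor=sigma_floor)
    best_loglik = classification_log_likelihood(data, best_clustering,
                                                p_floor=p_floor,
                                                sigma_floor=sigma_floor)
    k = count_parameters(best_clustering.n_clusters, data.n_r, data.n_e)
    best_obj = objective(best_loglik, k, spec, data.n)
    return SearchResult(
        best_clustering=best_clustering,
        best_model=best_model,
        best_objective=best_obj,
        best_loglik=best_loglik,
        trace=trace,
    )


def default_k_init(n: int) -> int:
    return max(2, min(n, n // 20))


def anneal(
    data: MixedDataset,
    spec: PenaltySpec,
    schedule: AnnealSchedule | None = None,
    k_init: int | None = None,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> SearchResult:
    """Run one simulated-annealing search, fully reproducible from
    ``schedule.seed``.  ``sigma_floor`` sets the finest noise scale the
    objective will resolve; raise it for noisier data."""
    schedule = schedule or AnnealSchedule()
    if k_init is None:
        k_init = default_k_init(data.n)
    rng = np.random.default_rng(schedule.seed)
    return _anneal_single(data, spec, schedule, k_init, rng,
                          p_floor=p_floor, sigma_floor=sigma_floor)


def anneal_restarts(
    data: MixedDataset,
    spec: PenaltySpec,
    schedule: AnnealSchedule | None = None,
    k_init: int | None = None,
    n_restarts: int = 3,
    p_floor: float = P_FLOOR,
    sigma_floor: float = SIGMA_FLOOR,
) -> SearchResult:
    """Run ``n_restarts`` independent searches from seeds derived from
    ``schedule.seed`` and keep the best objective (first-encountered wins
    ties)."""
    schedule = schedule or AnnealSchedule()
    seeds = np.random.SeedSequence(schedule.seed).spawn(n_restarts)
    best: SearchResult | None = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        res = _anneal_single(
            data, spec, schedule,
            k_init if k_init is not None else default_k_init(data.n), rng,
            p_floor=p_floor, sigma_floor=sigma_floor,
        )
        if best is None or res.best_objective < best.best_objective - 1e-12:
            best = res
    assert best is not None
    return best
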