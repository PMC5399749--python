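"""Unit and property tests for the mixture density, likelihoods and the
penalized objective."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import bernoulli, norm

from bgmix import (
    ComponentParams,
    HardClustering,
    MixedDataset,
    MixtureModel,
    PenaltySpec,
    classification_log_likelihood,
    count_parameters,
    fit_component_mle,
    log_component_density,
    log_likelihood_mixture,
    model_from_clustering,
    objective,
    penalty_value,
)
from bgmix.model import SIGMA_FLOOR

from conftest import random_dataset


def comp(p=(), mu=(), sigma=(), alpha=1.0):
    return ComponentParams(
        alpha=alpha, p=np.array(p, float), mu=np.array(mu, float),
        sigma=np.array(sigma, float),
    )


class TestLogComponentDensity:
    def test_single_bernoulli_half(self):
        c = comp(p=[0.5])
        assert log_component_density(c, np.array([1.0]), np.empty(0)) == \
            pytest.approx(math.log(0.5))

    def test_standard_normal_at_mode(self):
        c = comp(mu=[0.0], sigma=[1.0])
        assert log_component_density(c, np.empty(0), np.array([0.0])) == \
            pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_term_by_term_scipy_sum(self):
        # independent oracle: per-variable scipy densities summed directly
        c = comp(p=[0.9, 0.1], mu=[2.0], sigma=[0.5])
        r = np.array([1.0, 0.0])
        e = np.array([2.5])
        expected = (
            bernoulli.logpmf(1, 0.9)
            + bernoulli.logpmf(0, 0.1)
            + norm.logpdf(2.5, loc=2.0, scale=0.5)
        )
        assert log_component_density(c, r, e) == pytest.approx(expected)

    def test_dimension_mismatch_names_block(self):
        c = comp(p=[0.5], mu=[0.0], sigma=[1.0])
        with pytest.raises(ValueError, match="binary"):
            log_component_density(c, np.array([1.0, 0.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="continuous"):
            log_component_density(c, np.array([1.0]), np.empty(0))


class TestMixtureLogLikelihood:
    def test_identical_components_collapse(self, toy_dataset):
        c1 = comp(p=[0.6, 0.4], mu=[0.0, 0.0], sigma=[1.0, 1.0], alpha=0.5)
        c2 = comp(p=[0.6, 0.4], mu=[0.0, 0.0], sigma=[1.0, 1.0], alpha=0.5)
        two = MixtureModel(components=[c1, c2], n_r=2, n_e=2)
        one = MixtureModel(
            components=[comp(p=[0.6, 0.4], mu=[0.0, 0.0], sigma=[1.0, 1.0])],
            n_r=2, n_e=2,
        )
        assert log_likelihood_mixture(two, toy_dataset) == pytest.approx(
            log_likelihood_mixture(one, toy_dataset)
        )

    def test_single_component_single_point_is_density(self):
        data = MixedDataset(
            entity_ids=["a"], binary_names=["b"], continuous_names=["c"],
            R=np.array([[1.0]]), E=np.array([[0.3]]),
        )
        c = comp(p=[0.7], mu=[0.0], sigma=[1.0])
        model = MixtureModel(components=[c], n_r=1, n_e=1)
        assert log_likelihood_mixture(model, data) == pytest.approx(
            log_component_density(c, data.R[0], data.E[0])
        )

    def test_matches_naive_probability_space_sum(self):
        # brute-force oracle: evaluate the mixture density per point without
        # log-sum-exp and take logs directly
        rng = np.random.default_rng(5)
        data = random_dataset(rng, n=3, n_r=2, n_e=1)
        c1 = comp(p=[0.8, 0.3], mu=[0.5], sigma=[1.2], alpha=0.4)
        c2 = comp(p=[0.2, 0.6], mu=[-0.5], sigma=[0.7], alpha=0.6)
        model = MixtureModel(components=[c1, c2], n_r=2, n_e=1)
        expected = 0.0
        for i in range(data.n):
            dens = 0.0
            for c in model.components:
                dens += c.alpha * math.exp(
                    log_component_density(c, data.R[i], data.E[i])
                )
            expected += math.log(dens)
        assert log_likelihood_mixture(model, data) == pytest.approx(expected)

    def test_no_overflow_for_extreme_log_densities(self):
        # densities spanning roughly +/-700 in log space must not overflow
        data = MixedDataset(
            entity_ids=["a"], binary_names=[], continuous_names=["c"],
            R=np.zeros((1, 0)), E=np.array([[50.0]]),
        )
        far = comp(mu=[-50.0], sigma=[SIGMA_FLOOR], alpha=0.5)
        near = comp(mu=[50.0], sigma=[SIGMA_FLOOR], alpha=0.5)
        model = MixtureModel(components=[far, near], n_r=0, n_e=1)
        val = log_likelihood_mixture(model, data)
        assert np.isfinite(val)

    def test_permutation_invariance(self, tight_small):
        data, _ = tight_small
        cl = HardClustering.from_labels(np.arange(data.n) % 3)
        model = model_from_clustering(data, cl)
        perm_model = MixtureModel(
            components=list(reversed(model.components)),
            n_r=model.n_r, n_e=model.n_e,
        )
        order = np.random.default_rng(0).permutation(data.n)
        perm_data = MixedDataset(
            entity_ids=[data.entity_ids[i] for i in order],
            binary_names=data.binary_names,
            continuous_names=data.continuous_names,
            R=data.R[order], E=data.E[order],
        )
        base = log_likelihood_mixture(model, data)
        assert log_likelihood_mixture(perm_model, data) == pytest.approx(base)
        assert log_likelihood_mixture(model, perm_data) == pytest.approx(base)


class TestFitComponentMLE:
    def test_pure_column_is_clamped(self, toy_dataset):
        c = fit_component_mle(toy_dataset, [0, 1])
        assert c.p[0] == pytest.approx(1 - 1e-3)
        assert c.p[1] == pytest.approx(1e-3)

    def test_singleton_sigma_floored(self, toy_dataset):
        c = fit_component_mle(toy_dataset, [0])
        assert np.all(c.sigma == SIGMA_FLOOR)

    def test_two_point_population_sd(self):
        data = MixedDataset(
            entity_ids=["a", "b"], binary_names=[], continuous_names=["c"],
            R=np.zeros((2, 0)), E=np.array([[1.0], [3.0]]),
        )
        c = fit_component_mle(data, [0, 1])
        assert c.mu[0] == pytest.approx(2.0)
        assert c.sigma[0] == pytest.approx(1.0)  # population SD of {1, 3}

    def test_empty_member_set_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="empty"):
            fit_component_mle(toy_dataset, [])


class TestClassificationLogLikelihood:
    def test_point_mass_single_cluster(self):
        # all points identical: MLE sigma hits the floor, p is clamped
        n = 3
        data = MixedDataset(
            entity_ids=list("abc"), binary_names=["b"],
            continuous_names=["c"],
            R=np.ones((n, 1)), E=np.full((n, 1), 0.7),
        )
        cl = HardClustering.from_labels([0] * n)
        expected = n * (
            math.log(1 - 1e-3)
            + norm.logpdf(0.7, loc=0.7, scale=SIGMA_FLOOR)
        )  # ln alpha = ln 1 = 0
        assert classification_log_likelihood(data, cl) == pytest.approx(expected)

    def test_matches_independent_recomputation(self, toy_dataset):
        cl = HardClustering.from_labels([0, 0, 1, 1])
        # oracle: fit each half separately and accumulate all terms by hand
        expected = 0.0
        for m in (0, 1):
            idx = [i for i, z in enumerate([0, 0, 1, 1]) if z == m]
            c = fit_component_mle(toy_dataset, idx)
            for i in idx:
                expected += math.log(len(idx) / 4) + log_component_density(
                    c, toy_dataset.R[i], toy_dataset.E[i]
                )
        assert classification_log_likelihood(toy_dataset, cl) == \
            pytest.approx(expected)

    def test_hard_loglik_bounded_by_mixture_loglik(self, tight_small):
        data, _ = tight_small
        rng = np.random.default_rng(7)
        for _ in range(5):
            cl = HardClustering.from_labels(rng.integers(0, 4, size=data.n))
            hard = classification_log_likelihood(data, cl)
            soft = log_likelihood_mixture(model_from_clustering(data, cl), data)
            assert hard <= soft + 1e-9


class TestObjectiveAndPenalties:
    @pytest.mark.parametrize(
        "spec,n,expected",
        [
            (PenaltySpec("constant", 2.0), 500, 2.0),
            (PenaltySpec("bic"), 100, math.log(100)),
            (PenaltySpec("hannan_quinn"), 100, 2 * math.log(math.log(100))),
            (PenaltySpec("caic"), 100, 1 + math.log(100)),
        ],
    )
    def test_penalty_closed_forms(self, spec, n, expected):
        assert penalty_value(spec, n) == pytest.approx(expected)

    def test_penalty_small_n_rejected(self):
        with pytest.raises(ValueError):
            penalty_value(PenaltySpec("bic"), 1)
        with pytest.raises(ValueError):
            penalty_value(PenaltySpec("hannan_quinn"), 2)

    @pytest.mark.parametrize(
        "args,expected",
        [((1, 0, 1), 2), ((25, 20, 20), 1524), ((2, 1, 0), 3)],
    )
    def test_count_parameters(self, args, expected):
        assert count_parameters(*args) == expected

    @pytest.mark.parametrize(
        "L,k,spec,n,expected",
        [
            (0.0, 0, PenaltySpec("constant", 2.0), 10, 0.0),
            (-100.0, 10, PenaltySpec("constant", 2.0), 7, 220.0),
            (-100.0, 10, PenaltySpec("bic"), 100, 200 + 10 * math.log(100)),
        ],
    )
    def test_objective_arithmetic(self, L, k, spec, n, expected):
        assert objective(L, k, spec, n) == pytest.approx(expected)

    @given(
        lams=st.lists(
            st.integers(0, 400).map(lambda i: 1.0 + i * 0.01),
            min_size=2, max_size=5, unique=True,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_objective_increasing_in_lambda(self, lams):
        vals = [
            objective(-50.0, 7, PenaltySpec("constant", lam), 100)
            for lam in sorted(lams)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestInvariantsAndValidation:
    def test_weights_must_sum_to_one(self):
        c = comp(p=[0.5], alpha=0.6)
        with pytest.raises(ValueError, match="sum"):
            MixtureModel(components=[c, c], n_r=1, n_e=0)

    def test_dataset_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            MixedDataset(
                entity_ids=["a"], binary_names=["b"], continuous_names=[],
                R=np.array([[2.0]]), E=np.zeros((1, 0)),
            )

    def test_dataset_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            MixedDataset(
                entity_ids=["a"], binary_names=[], continuous_names=["c"],
                R=np.zeros((1, 0)), E=np.array([[np.nan]]),
            )

    def test_expression_only_dataset_allowed(self):
        d = MixedDataset(
            entity_ids=["a", "b"], binary_names=[], continuous_names=["c"],
            R=np.zeros((2, 0)), E=np.array([[0.1], [0.2]]),
        )
        assert d.n_r == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_log_densities_always_finite(self, seed):
        rng = np.random.default_rng(seed)
        data = random_dataset(rng, n=6, n_r=3, n_e=2)
        cl = HardClustering.from_labels(rng.integers(0, 3, size=6))
        assert np.isfinite(classification_log_likelihood(data, cl))
        model = model_from_clustering(data, cl)
        assert np.isfinite(log_likelihood_mixture(model, data))
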