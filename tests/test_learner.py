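"""Weight learning: sigmoid surrogate, margins, gradient, descent loop."""

import numpy as np
import pytest

from lhda import (
    FeatureWeights,
    LHDAConfig,
    LabeledDataset,
    compute_margin_terms,
    fit_weights,
    frozen_objective,
    generate_blobs,
    margin_ratio,
    objective_gradient,
    penalized_objective,
    screening_init,
    sigmoid_step,
    sigmoid_step_derivative,
)
from lhda.exceptions import ConfigurationError, ValidationError
from lhda.hyperplane import AlphaProblem, solve_spanning_coefficients

from conftest import random_dataset
from oracles import naive_penalized_objective


def _alpha_solver(x, H, w):
    return solve_spanning_coefficients(AlphaProblem.build(x, H, w), "exact")


class TestSigmoid:
    @pytest.mark.parametrize("beta", [0.5, 1.0, 5.0, 20.0])
    def test_half_at_unit_margin(self, beta):
        assert sigmoid_step(1.0, beta) == pytest.approx(0.5)

    def test_known_value(self):
        assert sigmoid_step(1.0 + np.log(3.0), 1.0) == pytest.approx(0.75)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 5.0, 20.0])
    def test_derivative_at_one(self, beta):
        assert sigmoid_step_derivative(1.0, beta) == pytest.approx(beta / 4.0)

    def test_monotone_and_stable(self):
        z = np.array([-1e6, -10.0, 0.0, 1.0, 10.0, 1e6])
        s = sigmoid_step(z, 5.0)
        assert np.all(np.diff(s) >= 0)
        assert np.all(np.isfinite(s)) and s[0] >= 0.0 and s[-1] <= 1.0


class TestMarginRatio:
    def test_equal_distances_give_unit_ratio(self):
        # mirror-symmetric classes: hit and miss neighbors equally far
        X = np.array([[0.0], [2.0], [-2.0], [4.0], [-4.0], [6.0], [-6.0]])
        y = np.array([1, 1, 2, 1, 2, 1, 2])
        ds = LabeledDataset(X, y)
        cfg = LHDAConfig(k=1)
        r, nh, nm = margin_ratio(0, ds, np.ones(1), cfg)
        assert nh.distance == pytest.approx(nm.distance)
        assert r == pytest.approx(1.0)

    def test_duplicate_in_own_class_zeroes_ratio(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.0], [5.0, 5.0], [6.0, 6.0]])
        y = np.array([1, 1, 1, 2, 2])
        ds = LabeledDataset(X, y)
        cfg = LHDAConfig(k=1)
        r, _, _ = margin_ratio(0, ds, np.ones(2), cfg)
        assert r == 0.0

    def test_duplicate_in_other_class_hits_cap(self):
        X = np.array([[1.0, 1.0], [3.0, 3.0], [0.0, 0.0], [1.0, 1.0], [6.0, 6.0]])
        y = np.array([1, 1, 1, 2, 2])
        ds = LabeledDataset(X, y)
        cfg = LHDAConfig(k=1, ratio_cap=1e6)
        r, nh, nm = margin_ratio(0, ds, np.ones(2), cfg)
        assert nm.distance == 0.0 and nh.distance > 0.0
        assert r == cfg.ratio_cap


class TestPenalizedObjective:
    def test_penalty_is_additive(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng, n_per_class=5, d=3)
        v = np.abs(rng.normal(size=3)) + 0.1
        j0 = penalized_objective(ds, v, LHDAConfig(k=2, lam=0.0))
        j1 = penalized_objective(ds, v, LHDAConfig(k=2, lam=1.0))
        assert j1 - j0 == pytest.approx(float(v @ v), abs=1e-12)

    def test_value_within_analytic_bounds(self):
        rng = np.random.default_rng(2)
        ds = random_dataset(rng, n_per_class=5, d=3)
        v = np.abs(rng.normal(size=3)) + 0.1
        cfg = LHDAConfig(k=2, lam=0.7)
        j = penalized_objective(ds, v, cfg)
        penalty = cfg.lam * float(v @ v)
        assert penalty <= j <= 1.0 + penalty

    def test_separated_classes_vanishing_error(self):
        ds = generate_blobs(n_per_class=8, informative_dims=1, noise_dim=0,
                            separation=50.0, seed=0)
        cfg = LHDAConfig(k=2, lam=0.0, beta=20.0)
        v = np.ones(1)
        assert penalized_objective(ds, v, cfg) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_straight_line_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_per_class=5, n_classes=2, d=3)
        v = np.abs(rng.normal(size=3)) + 0.2
        cfg = LHDAConfig(k=2, lam=0.5, beta=3.0)
        fast = penalized_objective(ds, v, cfg)
        naive = naive_penalized_objective(ds, v, cfg, _alpha_solver)
        assert fast == pytest.approx(naive, abs=1e-12)

    def test_zero_vector_rejected(self, blob_dataset):
        with pytest.raises(ValidationError):
            penalized_objective(blob_dataset, np.zeros(3), LHDAConfig(k=2))


class TestGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_per_class=6, d=4)
        cfg = LHDAConfig(k=2, lam=0.4, beta=4.0)
        v = np.abs(rng.normal(size=4)) + 0.3
        terms = compute_margin_terms(ds, v, cfg)
        grad = objective_gradient(ds, v, cfg, terms)
        h = 1e-6
        fd = np.empty_like(v)
        for j in range(v.size):
            vp, vm = v.copy(), v.copy()
            vp[j] += h
            vm[j] -= h
            fd[j] = (
                frozen_objective(terms, vp, cfg) - frozen_objective(terms, vm, cfg)
            ) / (2.0 * h)
        assert np.linalg.norm(fd - grad) <= 1e-5 * (1.0 + np.linalg.norm(grad))

    def test_duplicated_feature_symmetry(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(12, 2))
        X = np.column_stack([base[:, 0], base[:, 0], base[:, 1]])
        y = np.repeat([1, 2], 6)
        ds = LabeledDataset(X, y)
        cfg = LHDAConfig(k=2)
        v = np.array([0.8, 0.8, 0.5])
        terms = compute_margin_terms(ds, v, cfg)
        grad = objective_gradient(ds, v, cfg, terms)
        assert grad[0] == pytest.approx(grad[1], rel=1e-10)

    def test_zero_v_component_gets_zero_gradient(self):
        rng = np.random.default_rng(8)
        ds = random_dataset(rng, n_per_class=6, d=4)
        cfg = LHDAConfig(k=2)
        v = np.array([0.5, 0.0, 0.7, 0.0])
        terms = compute_margin_terms(ds, v, cfg)
        grad = objective_gradient(ds, v, cfg, terms)
        assert grad[1] == 0.0 and grad[3] == 0.0


class TestFitWeights:
    def test_blobs_informative_feature_wins(self):
        ds = generate_blobs(n_per_class=15, informative_dims=1, noise_dim=4,
                            separation=8.0, seed=2)
        weights, trace = fit_weights(ds, LHDAConfig(k=2))
        assert int(np.argmax(weights.w)) == 0
        assert trace.iterations_run >= 1

    def test_objective_trace_non_increasing(self, blob_dataset, tiny_config):
        _, trace = fit_weights(blob_dataset, tiny_config)
        diffs = np.diff(trace.objective_values)
        assert np.all(diffs <= 1e-12)

    def test_weights_structurally_nonnegative(self, blob_dataset, tiny_config):
        weights, _ = fit_weights(blob_dataset, tiny_config)
        assert np.all(weights.w >= 0)
        assert weights.w == pytest.approx(weights.v * weights.v)

    def test_sparsity_grows_with_penalty(self):
        ds = generate_blobs(n_per_class=10, informative_dims=1, noise_dim=3,
                            separation=8.0, seed=6)
        norms = []
        for lam in (0.1, 2.0):
            weights, _ = fit_weights(ds, LHDAConfig(k=2, lam=lam))
            norms.append(weights.w.sum())
        assert norms[1] <= norms[0]

    def test_small_class_rejected_before_iterating(self):
        X = np.vstack([np.zeros((2, 2)), np.ones((6, 2))])
        y = np.array([1, 1, 2, 2, 2, 2, 2, 2])
        ds = LabeledDataset(X, y)
        with pytest.raises(ConfigurationError):
            fit_weights(ds, LHDAConfig(k=2))

    def test_deterministic_given_data(self, blob_dataset, tiny_config):
        w1, _ = fit_weights(blob_dataset, tiny_config)
        w2, _ = fit_weights(blob_dataset, tiny_config)
        assert np.array_equal(w1.w, w2.w)

    def test_record_weights_snapshots(self, blob_dataset, tiny_config):
        _, trace = fit_weights(blob_dataset, tiny_config, record_weights=True)
        assert len(trace.weight_snapshots) == len(trace.objective_values)


class TestScreeningInit:
    def test_informative_feature_scores_higher(self):
        ds = generate_blobs(n_per_class=25, informative_dims=1, noise_dim=6,
                            separation=6.0, seed=4)
        v0 = screening_init(ds)
        w0 = v0 * v0
        assert int(np.argmax(w0)) == 0
        assert w0.sum() == pytest.approx(1.0)

    def test_all_noise_reduces_to_near_uniform(self):
        rng = np.random.default_rng(10)
        ds = random_dataset(rng, n_per_class=30, d=5)
        w0 = screening_init(ds) ** 2
        assert w0.max() / w0.min() < 50  # no feature dominates without signal
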