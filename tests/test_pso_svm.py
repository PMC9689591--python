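"""SVM fitting, swarm search mechanics, and sigmoid calibration."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from mifnn.evaluation import roc_auc
from mifnn.pso_svm import (
    DegenerateScores,
    NonPositiveHyperparameter,
    PlattParams,
    PSOConfig,
    PSOState,
    SingleClassDataset,
    cv_fitness,
    platt_calibrate,
    predict_proba,
    pso_init,
    pso_optimize,
    pso_step,
    rbf_kernel_value,
    svm_fit,
)


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=120, centers=[[-4.0, -4.0], [4.0, 4.0]],
                      cluster_std=0.8, random_state=4)
    return X, y


class TestSVMFit:
    def test_kernel_value_at_zero_distance(self, rng):
        f = rng.normal(size=8)
        assert rbf_kernel_value(f, f, g=0.7) == 1.0

    def test_separable_blobs_perfect_training_accuracy(self, blobs):
        X, y = blobs
        model = svm_fit(X, y, C=10.0, g=0.5)
        assert (model.predict(X) == y).mean() == 1.0

    def test_label_flip_negates_decision_values(self, blobs):
        X, y = blobs
        a = svm_fit(X, y, C=1.0, g=0.5).decision_function(X)
        b = svm_fit(X, 1 - y, C=1.0, g=0.5).decision_function(X)
        assert np.all(np.sign(a) == -np.sign(b))
        np.testing.assert_allclose(a, -b, atol=1e-2)  # libsvm solver tolerance

    def test_invalid_hyperparameters(self, blobs):
        X, y = blobs
        with pytest.raises(NonPositiveHyperparameter):
            svm_fit(X, y, C=0.0, g=1.0)
        with pytest.raises(NonPositiveHyperparameter):
            svm_fit(X, y, C=1.0, g=-1.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(SingleClassDataset):
            svm_fit(rng.normal(size=(10, 2)), np.zeros(10), C=1.0, g=1.0)

    def test_sigma_identification(self, blobs):
        X, y = blobs
        model = svm_fit(X, y, C=1.0, g=2.0)
        # g = 1/(2 sigma^2)
        assert model.sigma == pytest.approx(0.5)


class _ConstantRNG:
    """Stub generator: every uniform draw returns 0.5."""

    def random(self, shape=None):
        return np.full(shape, 0.5) if shape is not None else 0.5


class TestPSOStep:
    def _state_1d(self, pos, vel, pbest, gbest, box=(-100.0, 100.0)):
        cfg = PSOConfig(log2_c_range=box, log2_g_range=box,
                        n_particles=1, inertia=0.5, c1=1.0, c2=1.0)
        return PSOState(
            positions=np.array([[pos, 0.0]]),
            velocities=np.array([[vel, 0.0]]),
            pbest_positions=np.array([[pbest, 0.0]]),
            pbest_fitness=np.array([0.5]),
            gbest_position=np.array([gbest, 0.0]),
            gbest_fitness=0.4,
            config=cfg,
            rng=_ConstantRNG(),
        )

    def test_hand_arithmetic_update(self):
        # v' = 0.5*2 + 0.5*(3-1) + 0.5*(5-1) = 4 ; L' = 1 + 4 = 5
        state = self._state_1d(pos=1.0, vel=2.0, pbest=3.0, gbest=5.0)
        out = pso_step(state, lambda C, g: 1.0)
        assert out.velocities[0, 0] == pytest.approx(4.0)
        assert out.positions[0, 0] == pytest.approx(5.0)

    def test_fixed_point_particle_stays(self):
        state = self._state_1d(pos=2.0, vel=0.0, pbest=2.0, gbest=2.0)
        out = pso_step(state, lambda C, g: 1.0)
        assert out.positions[0, 0] == 2.0 and out.velocities[0, 0] == 0.0

    def test_gbest_trace_monotone_on_toy_problem(self):
        cfg = PSOConfig(n_particles=6, n_iterations=15, seed=3)
        fn = lambda C, g: (np.log2(C) - 2.0) ** 2 + (np.log2(g) + 3.0) ** 2
        state = pso_init(fn, cfg, np.random.default_rng(cfg.seed))
        for _ in range(cfg.n_iterations):
            state = pso_step(state, fn)
        trace = np.array(state.gbest_trace)
        assert np.all(np.diff(trace) <= 0)
        assert state.gbest_fitness <= trace[0]


class TestPSOOptimize:
    def test_perfect_classifier_has_zero_fitness(self, blobs):
        X, y = blobs
        fn = cv_fitness(X, y, PSOConfig(seed=0))
        assert fn(10.0, 0.5) == 0.0

    def test_beats_log_grid_with_shared_folds(self, blobs):
        X, y = blobs
        cfg = PSOConfig(n_particles=8, n_iterations=8, seed=1)
        fn = cv_fitness(X, y, cfg)
        C, g, state = pso_optimize(X, y, cfg)
        grid = [fn(2.0 ** lc, 2.0 ** lg)
                for lc in np.linspace(*cfg.log2_c_range, 5)
                for lg in np.linspace(*cfg.log2_g_range, 5)]
        assert state.gbest_fitness <= min(grid)

    def test_seeded_determinism(self, blobs):
        X, y = blobs
        cfg = PSOConfig(n_particles=5, n_iterations=5, seed=9)
        assert pso_optimize(X, y, cfg)[:2] == pso_optimize(X, y, cfg)[:2]

    def test_not_worse_than_random_search_at_equal_budget(self, blobs):
        X, y = blobs
        for seed in range(5):
            cfg = PSOConfig(n_particles=5, n_iterations=6, seed=seed)
            fn = cv_fitness(X, y, cfg)
            _, _, state = pso_optimize(X, y, cfg)
            budget = cfg.n_particles * (cfg.n_iterations + 1)
            rs = np.random.default_rng(seed + 1000)
            lo = np.array([cfg.log2_c_range[0], cfg.log2_g_range[0]])
            hi = np.array([cfg.log2_c_range[1], cfg.log2_g_range[1]])
            draws = rs.uniform(lo, hi, size=(budget, 2))
            random_best = min(fn(2.0 ** p[0], 2.0 ** p[1]) for p in draws)
            assert state.gbest_fitness <= random_best


class TestPlatt:
    def test_zero_parameters_give_half(self):
        p = PlattParams(A=0.0, B=0.0)
        np.testing.assert_allclose(p.probability(np.array([-5.0, 0.0, 7.0])), 0.5)

    def test_symmetric_scores_balanced_classes_give_zero_offset(self):
        scores = np.array([1.0] * 20 + [-1.0] * 20)
        labels = np.array([1] * 20 + [0] * 20)
        fitted = platt_calibrate(scores, labels)
        assert abs(fitted.B) < 1e-6
        assert fitted.A < 0  # higher score -> higher probability

    def test_fitted_map_is_monotone_on_random_separable_fits(self, rng):
        for _ in range(5):
            pos = rng.normal(loc=1.5, size=30)
            neg = rng.normal(loc=-1.5, size=30)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * 30 + [0] * 30)
            fitted = platt_calibrate(scores, labels)
            assert fitted.A < 0
            order = np.argsort(scores)
            probs = fitted.probability(scores[order])
            assert np.all(np.diff(probs) >= 0)

    def test_degenerate_scores_return_prior(self):
        scores = np.zeros(10)
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        fitted = platt_calibrate(scores, labels)
        assert fitted.A == 0.0
        assert fitted.probability(np.array([0.0]))[0] == pytest.approx(0.2)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassDataset):
            platt_calibrate(np.array([1.0, 2.0]), np.array([1, 1]))


@pytest.fixture(scope="module")
def calibrated(blobs):
    X, y = blobs
    model = svm_fit(X, y, C=10.0, g=0.5)
    platt = platt_calibrate(model.decision_function(X), y)
    return X, y, model, platt


class TestPredictProba:
    def test_outputs_in_open_unit_interval(self, calibrated):
        X, _, model, platt = calibrated
        p = predict_proba(model, platt, X)
        assert np.all((p > 0) & (p < 1))

    def test_ranking_matches_decision_values(self, calibrated):
        X, _, model, platt = calibrated
        dec = model.decision_function(X)
        p = predict_proba(model, platt, X)
        np.testing.assert_array_equal(np.argsort(dec), np.argsort(p))

    def test_interior_positive_point_high_probability(self, calibrated):
        X, y, model, platt = calibrated
        center = X[y == 1].mean(axis=0)
        assert predict_proba(model, platt, center[None, :])[0] > 0.9

    def test_calibration_preserves_auc_exactly(self, calibrated):
        X, y, model, platt = calibrated
        dec = model.decision_function(X)
        assert roc_auc(predict_proba(model, platt, X), y).auc == roc_auc(dec, y).auc
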