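"""RBF-kernel SVM with particle-swarm hyperparameter search and sigmoid
probability calibration.

The soft-margin dual problem is solved by scikit-learn's libsvm-backed SVC;
everything around it is authored here: the swarm search over (C, g) in log2
space, the cross-validated fitness (mean squared difference between predicted
and true 0/1 labels, i.e. the CV error rate, minimized), and the two-parameter
sigmoid map from decision values to posterior probabilities
P(y=1 | f) = 1 / (1 + exp(A*f + B)), fitted by a damped Newton iteration on
the regularized negative log-likelihood.

The kernel is kappa(x, x') = exp(-||x - x'||^2 / (2 sigma^2)); the searched
parameter g is identified with 1/(2 sigma^2), matching the SVC ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


class SingleClassDataset(ValueError):
    pass


class NonPositiveHyperparameter(ValueError):
    pass


class DegenerateScores(ValueError):
    pass


# --------------------------------------------------------------------------
# SVM
# --------------------------------------------------------------------------

@dataclass
class SVMModel:
    """A fitted RBF SVM; labels are mapped to {-1, +1} internally by libsvm."""

    svc: SVC
    C: float
    g: float

    @property
    def sigma(self) -> float:
        return float(1.0 / np.sqrt(2.0 * self.g))

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def support_coefficients(self) -> np.ndarray:
        return self.svc.dual_coef_[0]

    @property
    def intercept(self) -> float:
        return float(self.svc.intercept_[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(np.asarray(X, dtype=np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def rbf_kernel_value(x: np.ndarray, y: np.ndarray, g: float) -> float:
    """kappa(x, y) = exp(-g * ||x - y||^2); equals 1 at zero distance."""
    d = np.asarray(x, float) - np.asarray(y, float)
    return float(np.exp(-g * np.dot(d, d)))


def svm_fit(features, labels, C: float, g: float) -> SVMModel:
    """Fit the soft-margin RBF SVM at penalty ``C`` and kernel parameter ``g``."""
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if C <= 0 or g <= 0:
        raise NonPositiveHyperparameter(f"C and g must be positive, got C={C}, g={g}")
    if len(np.unique(y)) < 2:
        raise SingleClassDataset("SVM fitting requires both classes")
    svc = SVC(C=C, gamma=g, kernel="rbf")
    svc.fit(X, y)
    return SVMModel(svc=svc, C=float(C), g=float(g))


# --------------------------------------------------------------------------
# Particle swarm optimization over (C, g)
# --------------------------------------------------------------------------

@dataclass
class PSOConfig:
    """Search box (log2 space) and swarm dynamics; none of these are critical
    and all are exposed."""

    log2_c_range: tuple[float, float] = (-5.0, 15.0)
    log2_g_range: tuple[float, float] = (-15.0, 3.0)
    n_particles: int = 20
    n_iterations: int = 30
    inertia: float = 0.8
    c1: float = 2.0
    c2: float = 2.0
    n_folds: int = 3
    seed: int = 0


@dataclass
class PSOState:
    positions: np.ndarray  # (n, 2) in log2(C), log2(g)
    velocities: np.ndarray  # (n, 2)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    config: PSOConfig
    rng: np.random.Generator
    iteration: int = 0
    gbest_trace: list[float] = field(default_factory=list)

    @property
    def bounds(self) -> np.ndarray:
        c = self.config
        return np.array([c.log2_c_range, c.log2_g_range])


def _evaluate_swarm(positions: np.ndarray, fitness_fn) -> np.ndarray:
    return np.array([fitness_fn(2.0 ** p[0], 2.0 ** p[1]) for p in positions])


def pso_init(fitness_fn, config: PSOConfig, rng: np.random.Generator) -> PSOState:
    bounds = np.array([config.log2_c_range, config.log2_g_range])
    pos = rng.uniform(bounds[:, 0], bounds[:, 1], size=(config.n_particles, 2))
    half_width = (bounds[:, 1] - bounds[:, 0]) / 2.0
    vel = rng.uniform(-half_width, half_width, size=(config.n_particles, 2)) * 0.1
    fit = _evaluate_swarm(pos, fitness_fn)
    best = int(np.argmin(fit))
    state = PSOState(
        positions=pos,
        velocities=vel,
        pbest_positions=pos.copy(),
        pbest_fitness=fit.copy(),
        gbest_position=pos[best].copy(),
        gbest_fitness=float(fit[best]),
        config=config,
        rng=rng,
    )
    state.gbest_trace.append(state.gbest_fitness)
    return state


def pso_step(state: PSOState, fitness_fn) -> PSOState:
    """One swarm update: v <- U v + c1 r1 (Pbest - L) + c2 r2 (Gbest - L);
    L <- L + v, with velocity clamped to half the box width and positions
    clipped to the box.  Personal/global bests updated (minimization)."""
    cfg = state.config
    n = cfg.n_particles
    r1 = state.rng.random((n, 2))
    r2 = state.rng.random((n, 2))
    v = (cfg.inertia * state.velocities
         + cfg.c1 * r1 * (state.pbest_positions - state.positions)
         + cfg.c2 * r2 * (state.gbest_position - state.positions))
    bounds = state.bounds
    half_width = (bounds[:, 1] - bounds[:, 0]) / 2.0
    v = np.clip(v, -half_width, half_width)
    pos = np.clip(state.positions + v, bounds[:, 0], bounds[:, 1])
    fit = _evaluate_swarm(pos, fitness_fn)
    improved = fit < state.pbest_fitness
    state.pbest_positions[improved] = pos[improved]
    state.pbest_fitness[improved] = fit[improved]
    best = int(np.argmin(state.pbest_fitness))
    if state.pbest_fitness[best] < state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[best])
        state.gbest_position = state.pbest_positions[best].copy()
    state.positions = pos
    state.velocities = v
    state.iteration += 1
    state.gbest_trace.append(state.gbest_fitness)
    return state


def cv_fitness(features, labels, config: PSOConfig):
    """CV fitness of a (C, g) pair: mean squared difference between predicted
    and true 0/1 labels under stratified k-fold cross-validation (equals the
    CV misclassification rate; a perfect classifier scores 0)."""
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    def fitness(C: float, g: float) -> float:
        errs = []
        for train_idx, test_idx in folds:
            model = svm_fit(X[train_idx], y[train_idx], C, g)
            pred = model.predict(X[test_idx])
            errs.append(np.mean((pred - y[test_idx]) ** 2))
        return float(np.mean(errs))

    return fitness


def pso_optimize(features, labels, config: PSOConfig | None = None):
    """Swarm-search (C, g) minimizing the cross-validated fitness.

    Returns ``(C*, g*, state)`` where the state carries the (monotone
    non-increasing) global-best fitness trace.
    """
    config = config or PSOConfig()
    fitness_fn = cv_fitness(features, labels, config)
    rng = np.random.default_rng(config.seed)
    state = pso_init(fitness_fn, config, rng)
    for _ in range(config.n_iterations):
        state = pso_step(state, fitness_fn)
    C_star = float(2.0 ** state.gbest_position[0])
    g_star = float(2.0 ** state.gbest_position[1])
    return C_star, g_star, state


# --------------------------------------------------------------------------
# Sigmoid (Platt) calibration
# --------------------------------------------------------------------------

@dataclass
class PlattParams:
    A: float
    B: float

    def probability(self, decision_values: np.ndarray) -> np.ndarray:
        z = self.A * np.asarray(decision_values, dtype=np.float64) + self.B
        return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def platt_calibrate(decision_values, labels) -> PlattParams:
    """Fit P(y=1|f) = 1/(1 + exp(A f + B)) by regularized maximum likelihood.

    Uses the damped Newton iteration with smoothed targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), which keeps the fit finite on
    separable score sets.  If all scores are identical the slope is pinned to
    A = 0 and B reproduces the class prior.
    """
    f = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassDataset("calibration requires both classes")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if np.allclose(f, f[0]):
        prior = n_pos / (n_pos + n_neg)
        return PlattParams(A=0.0, B=float(np.log((1 - prior) / prior)))

    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)

    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    eps = 1e-12

    def nll(a, b):
        z = a * f + b
        # -sum t*log(p) + (1-t)*log(1-p) with p = 1/(1+exp(z));
        # each term reduces to t*z + log(1+exp(-z)), computed stably per sign
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-np.abs(z))),
                                     (t - 1.0) * z + np.log1p(np.exp(-np.abs(z))))))

    old = nll(A, B)
    for _ in range(100):
        z = A * f + B
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # P(y=1)
        d1 = p - t  # gradient pieces: dNLL/dz = p - t ... sign per Platt param.
        w = p * (1.0 - p)
        g_a = float(np.dot(f, -d1))
        g_b = float(np.sum(-d1))
        h_aa = float(np.dot(f * f, w)) + eps
        h_ab = float(np.dot(f, w))
        h_bb = float(np.sum(w)) + eps
        det = h_aa * h_bb - h_ab * h_ab
        dA = -(h_bb * g_a - h_ab * g_b) / det
        dB = -(h_aa * g_b - h_ab * g_a) / det
        step = 1.0
        while step >= 1e-10:
            newA, newB = A + step * dA, B + step * dB
            if nll(newA, newB) < old + 1e-12:
                A, B, old = newA, newB, nll(newA, newB)
                break
            step /= 2.0
        if abs(g_a) < 1e-9 and abs(g_b) < 1e-9:
            break
    return PlattParams(A=float(A), B=float(B))


def predict_proba(model: SVMModel, platt: PlattParams, features) -> np.ndarray:
    """Posterior probability of the positive class for each feature row."""
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    return platt.probability(model.decision_function(X))
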