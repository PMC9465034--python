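"""Gaussian-kernel SVM with particle-swarm hyperparameter search.

The kernel width gamma and penalty C are found by global-best PSO over a
log-scaled search box; each particle's fitness is the stratified k-fold
cross-validation accuracy of an RBF SVM at its (gamma, C). After the search
the model is refitted on the full training data at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = ["PSOConfig", "PSOSVMResult", "train_pso_svm", "cv_fitness"]


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    iterations: int = 100
    gamma_range: tuple[float, float] = (1e-3, 1e2)
    C_range: tuple[float, float] = (1e-2, 1e3)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        for lo, hi in (self.gamma_range, self.C_range):
            if not (0 < lo < hi < np.inf):
                raise ValueError("search ranges must be positive and finite")


def cv_fitness(X: np.ndarray, y: np.ndarray, gamma: float, C: float,
               folds: int, seed: int = 0) -> float:
    """Stratified k-fold CV accuracy of an RBF SVM at (gamma, C)."""
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("need at least 2 samples per class for CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(SVC(kernel="rbf", gamma=gamma, C=C), X, y,
                             cv=skf)
    return float(scores.mean())


@dataclass
class PSOSVMResult:
    model: SVC
    gamma: float
    C: float
    fitness: float
    trace: np.ndarray  # best CV fitness after each PSO iteration


def train_pso_svm(X: np.ndarray, y: np.ndarray,
                  config: PSOConfig = PSOConfig(),
                  seed: int = 0) -> PSOSVMResult:
    """Maximize CV accuracy over (gamma, C) with global-best PSO, then refit
    on all data at the optimum. The returned trace is nondecreasing."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("feature matrix is empty")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")

    rng = np.random.default_rng(seed)
    lo = np.log10([config.gamma_range[0], config.C_range[0]])
    hi = np.log10([config.gamma_range[1], config.C_range[1]])
    pos = rng.uniform(lo, hi, size=(config.swarm_size, 2))
    vel = np.zeros_like(pos)
    vmax = 0.25 * (hi - lo)

    def fit_at(p) -> float:
        return cv_fitness(X, y, gamma=10 ** p[0], C=10 ** p[1],
                          folds=config.cv_folds, seed=seed)

    pbest = pos.copy()
    pbest_f = np.array([fit_at(p) for p in pos])
    g = int(np.argmax(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    trace = []
    for _ in range(config.iterations):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i, p in enumerate(pos):
            f = fit_at(p)
            if f > pbest_f[i]:
                pbest[i], pbest_f[i] = p.copy(), f
                if f > gbest_f:
                    gbest, gbest_f = p.copy(), f
        trace.append(gbest_f)

    gamma, C = 10 ** gbest[0], 10 ** gbest[1]
    model = SVC(kernel="rbf", gamma=gamma, C=C).fit(X, y)
    return PSOSVMResult(model=model, gamma=float(gamma), C=float(C),
                        fitness=gbest_f, trace=np.asarray(trace))
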