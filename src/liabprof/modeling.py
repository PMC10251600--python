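"""Regressors and hyperparameter tuning.

Three algorithms map chemical features to pACTIVITY:

* ``mlr`` — multi-linear regression baseline (ordinary least squares with a
  ridge-stabilised fallback when the design is rank-deficient, as it always
  is with 2059 features and fewer compounds);
* ``rf`` — random forest;
* ``gb`` — histogram-based gradient boosting (LightGBM), whose
  hyperparameters cover trees, depth, learning rate, leaf size, L1/L2
  regularization and the histogram bin count.

Tuning is a hybrid: a Latin-hypercube sample of the hyperparameter space
seeds a genetic algorithm whose objective is 5-fold cross-validated RMSE on
the training partition only. Early stopping triggers on five consecutive
stagnant generations or a wall-clock budget.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from lightgbm import LGBMRegressor

__all__ = [
    "ParamDef",
    "HyperparameterSpace",
    "GB_SPACE",
    "RF_SPACE",
    "sample_lhs",
    "QSARRegressor",
    "GeneticTuner",
    "tune",
    "fit_model",
    "select_champion",
]


@dataclass(frozen=True)
class ParamDef:
    """Bounds for one hyperparameter. ``scale`` is 'linear' or 'log'."""

    low: float
    high: float
    kind: str = "float"  # 'float' | 'int'
    scale: str = "linear"

    def decode(self, u: float):
        """Map a unit-interval coordinate to a parameter value."""
        if self.scale == "log":
            lo, hi = np.log(self.low), np.log(self.high)
            val = float(np.exp(lo + u * (hi - lo)))
        else:
            val = float(self.low + u * (self.high - self.low))
        if self.kind == "int":
            val = int(round(val))
            val = int(min(max(val, self.low), self.high))
        return val


HyperparameterSpace = dict[str, ParamDef]

#: Default gradient-boosting search space.
GB_SPACE: HyperparameterSpace = {
    "n_estimators": ParamDef(50, 1000, "int"),
    "max_depth": ParamDef(2, 12, "int"),
    "learning_rate": ParamDef(0.01, 0.3, "float", "log"),
    "min_child_samples": ParamDef(1, 30, "int"),  # leaf size
    "reg_alpha": ParamDef(0.0, 10.0),  # L1
    "reg_lambda": ParamDef(0.0, 10.0),  # L2
    "max_bin": ParamDef(20, 100, "int"),  # histogram bins
}

#: Default random-forest search space.
RF_SPACE: HyperparameterSpace = {
    "n_estimators": ParamDef(100, 1000, "int"),
    "max_depth": ParamDef(4, 20, "int"),
    "min_samples_leaf": ParamDef(1, 10, "int"),
    "max_features": ParamDef(0.2, 1.0),
}


def default_space(algorithm: str) -> HyperparameterSpace:
    return dict(GB_SPACE if algorithm == "gb" else RF_SPACE)


def sample_lhs(space: HyperparameterSpace, n: int, seed: int = 0) -> list[dict]:
    """Latin-hypercube sample of ``n`` configurations.

    For every parameter the n samples occupy n distinct equal-width strata of
    its (transformed) range — one sample per stratum. Deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(space)
    unit = qmc.LatinHypercube(d=len(names), seed=seed).random(n)
    return [
        {name: space[name].decode(unit[i, j]) for j, name in enumerate(names)}
        for i in range(n)
    ]


def _unit_lhs(d: int, n: int, seed: int) -> np.ndarray:
    return qmc.LatinHypercube(d=d, seed=seed).random(n)


class QSARRegressor(RegressorMixin, BaseEstimator):
    """A pACTIVITY regressor with an attached training fingerprint store.

    Parameters
    ----------
    algorithm : {'mlr', 'rf', 'gb'}
    hyperparams : dict | None
        Algorithm hyperparameters (ignored by 'mlr').
    seed : int
        Random seed; refitting with identical inputs and seed reproduces
        predictions exactly.

    Attributes
    ----------
    model_ : fitted underlying estimator
    ridge_fallback_ : bool
        True when the MLR design was rank-deficient and a ridge-stabilised
        solution was used instead of plain least squares.
    fingerprint_store_ : ndarray | None
        The training compounds' 2048-bit similarity vectors, retained for
        applicability-domain assessment when passed to :meth:`fit`.
    """

    def __init__(self, algorithm: str = "gb", hyperparams: dict | None = None, seed: int = 0):
        self.algorithm = algorithm
        self.hyperparams = hyperparams
        self.seed = seed

    def _build(self):
        hp = dict(self.hyperparams or {})
        if self.algorithm == "gb":
            hp.setdefault("n_estimators", 300)
            hp.setdefault("max_depth", 6)
            hp.setdefault("learning_rate", 0.1)
            hp.setdefault("min_child_samples", 5)
            return LGBMRegressor(
                random_state=self.seed,
                n_jobs=1,
                verbose=-1,
                num_leaves=2 ** 12,  # depth is the binding constraint
                **hp,
            )
        if self.algorithm == "rf":
            hp.setdefault("n_estimators", 300)
            return RandomForestRegressor(random_state=self.seed, n_jobs=1, **hp)
        if self.algorithm == "mlr":
            return None
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def fit(self, X, y, fingerprints: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        self.ridge_fallback_ = False
        if self.algorithm == "mlr":
            n, p = X.shape
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
            if rank < p + 1:
                # rank-deficient design: ridge-stabilised least squares
                self.ridge_fallback_ = True
                self.model_ = Ridge(alpha=1e-2).fit(X, y)
            else:
                from sklearn.linear_model import LinearRegression

                self.model_ = LinearRegression().fit(X, y)
        else:
            self.model_ = self._build().fit(X, y)
        self.fingerprint_store_ = (
            np.asarray(fingerprints, dtype=np.uint8) if fingerprints is not None else None
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper registers feature names even for
            # plain arrays, tripping sklearn's name check on predict
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            pred = self.model_.predict(np.asarray(X, dtype=float))
        return np.asarray(pred, dtype=float)


def fit_model(
    X, y, algorithm: str = "gb", config: dict | None = None, seed: int = 0,
    fingerprints: np.ndarray | None = None,
) -> QSARRegressor:
    """Convenience wrapper: build and fit a :class:`QSARRegressor`."""
    return QSARRegressor(algorithm, config, seed).fit(X, y, fingerprints=fingerprints)


def _cv_rmse(estimator_params: dict, algorithm: str, X, y, folds, seed: int) -> float:
    """5-fold cross-validated RMSE of one configuration on fixed folds."""
    errs = []
    for tr, va in folds:
        model = QSARRegressor(algorithm, estimator_params, seed).fit(X[tr], y[tr])
        pred = model.predict(X[va])
        errs.append(np.mean((y[va] - pred) ** 2) * len(va))
    return float(np.sqrt(np.sum(errs) / len(y)))


@dataclass
class TuningTrace:
    evaluations: list[tuple[dict, float]] = field(default_factory=list)
    generations: int = 0
    stopped_on: str = "generations"

    @property
    def best(self) -> tuple[dict, float]:
        return min(self.evaluations, key=lambda e: e[1])


class GeneticTuner(BaseEstimator):
    """LHS-seeded genetic hyperparameter search minimising CV-RMSE.

    A Latin-hypercube design initialises the population; evolution proceeds
    by tournament selection (size 3), uniform crossover and per-gene uniform
    mutation with single-elite carryover. The objective is k-fold CV RMSE on
    the data passed to :meth:`fit`, with folds fixed once per run so every
    candidate is scored on identical resamples. Stops after
    ``stagnation_limit`` generations without improvement or when the
    wall-clock ``time_budget`` is exhausted.

    Attributes
    ----------
    best_params_ : dict
    best_score_ : float  (CV RMSE, lower is better)
    trace_ : TuningTrace  (every evaluated configuration and score)
    """

    def __init__(
        self,
        algorithm: str = "gb",
        space: HyperparameterSpace | None = None,
        n_init: int = 20,
        population_size: int = 20,
        max_generations: int = 30,
        stagnation_limit: int = 5,
        time_budget: float = 300.0,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        tournament_size: int = 3,
        cv: int = 5,
        seed: int = 0,
    ):
        self.algorithm = algorithm
        self.space = space
        self.n_init = n_init
        self.population_size = population_size
        self.max_generations = max_generations
        self.stagnation_limit = stagnation_limit
        self.time_budget = time_budget
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.tournament_size = tournament_size
        self.cv = cv
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        space = dict(self.space) if self.space else default_space(self.algorithm)
        names = list(space)
        d = len(names)
        rng = np.random.default_rng(self.seed)
        t0 = time.monotonic()
        folds = list(
            KFold(n_splits=self.cv, shuffle=True, random_state=self.seed).split(X)
        )
        trace = TuningTrace()
        cache: dict[tuple, float] = {}

        def decode(gene: np.ndarray) -> dict:
            return {name: space[name].decode(gene[j]) for j, name in enumerate(names)}

        def score(gene: np.ndarray) -> float:
            params = decode(gene)
            key = tuple(sorted(params.items()))
            if key not in cache:
                if trace.evaluations and time.monotonic() - t0 > self.time_budget:
                    raise _BudgetExhausted
                cache[key] = _cv_rmse(params, self.algorithm, X, y, folds, self.seed)
                trace.evaluations.append((params, cache[key]))
            return cache[key]

        # LHS design seeds the population; pad with uniform genes if needed
        pop = _unit_lhs(d, self.n_init, self.seed)
        if self.n_init < self.population_size:
            pop = np.vstack([pop, rng.random((self.population_size - self.n_init, d))])
        try:
            fitness = np.array([score(g) for g in pop])
            keep = np.argsort(fitness)[: self.population_size]
            pop, fitness = pop[keep], fitness[keep]
            if not trace.evaluations:
                raise RuntimeError("tuning budget exhausted before any evaluation")
            best = float(fitness.min())
            stagnant = 0
            for gen in range(self.max_generations):
                trace.generations = gen + 1
                elite = pop[int(np.argmin(fitness))].copy()
                children = [elite]
                while len(children) < self.population_size:
                    pa = self._tournament(pop, fitness, rng)
                    pb = self._tournament(pop, fitness, rng)
                    child = pa.copy()
                    if rng.random() < self.crossover_prob:
                        swap = rng.random(d) < 0.5
                        child[swap] = pb[swap]
                    mutate = rng.random(d) < self.mutation_prob
                    child[mutate] = rng.random(int(mutate.sum()))
                    children.append(child)
                pop = np.vstack(children)
                fitness = np.array([score(g) for g in pop])
                gen_best = float(fitness.min())
                if gen_best < best - 1e-12:
                    best = gen_best
                    stagnant = 0
                else:
                    stagnant += 1
                if stagnant >= self.stagnation_limit:
                    trace.stopped_on = "stagnation"
                    break
        except _BudgetExhausted:
            trace.stopped_on = "time_budget"
        if not trace.evaluations:
            raise RuntimeError("tuning budget exhausted before any evaluation")
        self.best_params_, self.best_score_ = trace.best
        self.trace_ = trace
        return self

    def _tournament(self, pop, fitness, rng):
        idx = rng.integers(len(pop), size=self.tournament_size)
        return pop[idx[np.argmin(fitness[idx])]]


class _BudgetExhausted(Exception):
    pass


def tune(
    X, y, algorithm: str = "gb", space: HyperparameterSpace | None = None,
    seed: int = 0, **budget,
) -> GeneticTuner:
    """Run hyperparameter tuning; returns the fitted :class:`GeneticTuner`."""
    return GeneticTuner(algorithm=algorithm, space=space, seed=seed, **budget).fit(X, y)


def select_champion(candidates: list[tuple[QSARRegressor, float]]) -> QSARRegressor:
    """Pick the model with the highest external Pearson R; ties favour GB."""
    finite = [(m, r) for m, r in candidates if np.isfinite(r)]
    if not finite:
        raise ValueError("no candidate with a finite Pearson R")
    return max(finite, key=lambda mr: (mr[1], mr[0].algorithm == "gb"))[0]
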