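"""Genetic-algorithm optimization of composite-score weights.

A candidate solution is a real weight vector w, one entry per standardized
feature; its composite score for a participant is the plain dot product
s = w . x (no intercept — the intercept is absorbed downstream by Platt
calibration). Fitness is the mean held-out AUC of the composite score over
stratified inner K-fold splits of the training data, so the GA optimizes a
cross-validated estimate of discrimination rather than in-sample fit.

The GA is generational: uniform random initialization inside
``weight_init_range``, tournament selection, arithmetic blend crossover,
per-gene Gaussian mutation, and elitism. The best individual *ever*
evaluated is returned. Every stochastic component flows through one
``numpy`` generator seeded from the config, so a run is bit-reproducible.
The whole population is scored in one matrix product per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, SchemaError, StratificationError
from .metrics import auc_columns


@dataclass
class GAConfig:
    """Evolution hyperparameters. Defaults are package choices, all
    configurable; the seed fixes every stochastic component."""

    population_size: int = 60
    n_generations: int = 40
    weight_init_range: tuple[float, float] = (-1.0, 1.0)
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    mutation_sigma: float = 0.1
    tournament_size: int = 3
    elitism_count: int = 1
    inner_k: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be at least 2")
        if self.population_size < self.tournament_size:
            raise ConfigurationError("population_size must be >= tournament_size")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.mutation_sigma <= 0:
            raise ConfigurationError("mutation_sigma must be positive")
        if self.inner_k < 2:
            raise ConfigurationError("inner_k must be at least 2")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be non-negative")
        if not 0 <= self.elitism_count < self.population_size:
            raise ConfigurationError("elitism_count must be in [0, population_size)")
        lo, hi = self.weight_init_range
        if not lo < hi:
            raise ConfigurationError("weight_init_range must be a nonempty interval")

    def to_json_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "n_generations": self.n_generations,
            "weight_init_range": list(self.weight_init_range),
            "crossover_prob": self.crossover_prob,
            "mutation_prob": self.mutation_prob,
            "mutation_sigma": self.mutation_sigma,
            "tournament_size": self.tournament_size,
            "elitism_count": self.elitism_count,
            "inner_k": self.inner_k,
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GAConfig":
        d = dict(d)
        if "weight_init_range" in d:
            d["weight_init_range"] = tuple(d["weight_init_range"])
        return cls(**d)


def composite_score(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Linear composite score s_i = sum_j w_j x_ij."""
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or w.ndim != 1 or X.shape[1] != w.shape[0]:
        raise SchemaError(
            f"dimension mismatch: X is {X.shape}, w has length {w.shape[0] if w.ndim == 1 else '?'}"
        )
    return X @ w


def _inner_folds(y: np.ndarray, inner_k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both outcome classes must be present")
    if counts.min() < inner_k:
        raise StratificationError(
            f"minority class has {counts.min()} members; cannot build {inner_k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _population_fitness(
    W: np.ndarray, X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Mean held-out AUC per individual, whole population at once."""
    S = X @ W.T  # (n, pop)
    fits = np.zeros(W.shape[0])
    for _, test_idx in folds:
        fits += auc_columns(S[test_idx], y[test_idx])
    return fits / len(folds)


def cv_fitness(w: np.ndarray, X: np.ndarray, y, inner_k: int = 5, seed: int = 42) -> float:
    """Stratified inner-CV fitness of one weight vector: mean over
    ``inner_k`` shuffled stratified folds of the held-out midrank AUC of
    X . w. Fold assignment is deterministic given the seed."""
    y = np.asarray(y, dtype=int)
    w = np.asarray(w, dtype=float)
    folds = _inner_folds(y, inner_k, seed)
    return float(_population_fitness(w[None, :], np.asarray(X, dtype=float), y, folds)[0])


@dataclass
class EvolutionResult:
    """Best-ever weight vector plus the per-generation evolution log."""

    weights: np.ndarray
    best_fitness: float
    log: pd.DataFrame  # generation, best_fitness, mean_fitness, best_ever_fitness

    def weights_by_name(self, feature_names: list[str]) -> dict[str, float]:
        if len(feature_names) != len(self.weights):
            raise SchemaError("feature_names length does not match weight vector")
        return dict(zip(feature_names, map(float, self.weights)))


def evolve(X: np.ndarray, y, config: GAConfig) -> EvolutionResult:
    """Evolve a weight vector maximizing cross-validated composite AUC.

    Generation 0 is the uniformly-initialized random population; with
    ``n_generations=0`` the best of that initial population is returned.
    Elitism carries the ``elitism_count`` fittest individuals forward
    unchanged, so best-ever fitness is non-decreasing across generations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise SchemaError("X and y are inconsistent")
    d = X.shape[1]
    rng = np.random.default_rng(config.seed)
    folds = _inner_folds(y, config.inner_k, config.seed)
    lo, hi = config.weight_init_range

    pop = rng.uniform(lo, hi, size=(config.population_size, d))
    fits = _population_fitness(pop, X, y, folds)

    best_idx = int(np.argmax(fits))
    best_w = pop[best_idx].copy()
    best_fit = float(fits[best_idx])
    rows = [(0, float(fits.max()), float(fits.mean()), best_fit)]

    n_off = config.population_size - config.elitism_count
    for gen in range(1, config.n_generations + 1):
        elite_idx = np.argsort(fits)[::-1][: config.elitism_count]
        elites = pop[elite_idx].copy()

        # tournament selection of two parents per offspring
        cand = rng.integers(0, config.population_size, size=(n_off, 2, config.tournament_size))
        winners = cand[
            np.arange(n_off)[:, None],
            np.arange(2)[None, :],
            np.argmax(fits[cand], axis=2),
        ]
        p1, p2 = pop[winners[:, 0]], pop[winners[:, 1]]

        do_cx = rng.random(n_off) < config.crossover_prob
        alpha = rng.random((n_off, d))
        children = np.where(do_cx[:, None], alpha * p1 + (1.0 - alpha) * p2, p1)

        mut = rng.random((n_off, d)) < config.mutation_prob
        children = children + mut * rng.normal(0.0, config.mutation_sigma, size=(n_off, d))

        pop = np.vstack([elites, children]) if config.elitism_count else children
        fits = _population_fitness(pop, X, y, folds)

        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_w = pop[gen_best].copy()
        rows.append((gen, float(fits.max()), float(fits.mean()), best_fit))

    log = pd.DataFrame(rows, columns=["generation", "best_fitness", "mean_fitness", "best_ever_fitness"])
    return EvolutionResult(best_w, best_fit, log)
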