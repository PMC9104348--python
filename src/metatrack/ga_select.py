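"""Genetic-algorithm feature selection minimizing PLS RMSECV.

A binary-inclusion chromosome marks the features in a candidate panel; its
fitness is the minimum venetian-blind cross-validated RMSECV of a PLS model
with 1..max_latent_variables components on the autoscaled selected
submatrix. Chromosomes evolve by tournament selection, crossover and
bit-flip mutation; the best chromosome ever seen always survives
(elitism), which makes the fitness trace monotone non-increasing. The run
is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemometrics import ModelError, pls_rmsecv


@dataclass
class GaConfig:
    population_size: int = 64
    max_generations: int = 100
    mutation_rate: float = 0.005
    initial_inclusion_prob: float = 0.15
    crossover: str = "double"  # "single" or "double"
    max_latent_variables: int = 3
    cv_folds: int = 10
    convergence_fraction: float = 0.5
    max_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ModelError("population_size must be >= 2")
        if self.population_size % 2:
            raise ModelError("population_size must be even")
        for name in ("mutation_rate", "initial_inclusion_prob", "convergence_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ModelError(f"{name} must be in (0, 1), got {v}")
        if self.crossover not in ("single", "double"):
            raise ModelError(f"crossover must be 'single' or 'double', got {self.crossover!r}")


@dataclass
class GaResult:
    selected: list[str]
    selected_mask: np.ndarray
    best_rmsecv: float
    fitness_trace: list[float] = field(default_factory=list)
    generations_run: int = 0
    config: GaConfig | None = None


def _fitness(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    config: GaConfig,
    cache: dict,
) -> float:
    key = mask.tobytes()
    if key in cache:
        return cache[key]
    if not mask.any() or (config.max_features and mask.sum() > config.max_features):
        fit = float("inf")
    else:
        fit = pls_rmsecv(
            X[:, mask],
            y,
            max_components=config.max_latent_variables,
            n_folds=min(config.cv_folds, X.shape[0]),
        )
    cache[key] = fit
    return fit


def _crossover(a: np.ndarray, b: np.ndarray, mode: str, rng: np.random.Generator):
    p = a.size
    if mode == "single" or p < 3:  # double-point needs >= 3 loci
        cut = rng.integers(1, p)
        lo, hi = cut, p
    else:
        c1, c2 = sorted(rng.choice(np.arange(1, p), size=2, replace=False))
        lo, hi = c1, c2
    c, d = a.copy(), b.copy()
    c[lo:hi], d[lo:hi] = b[lo:hi], a[lo:hi]
    return c, d


def ga_feature_select(
    X: np.ndarray,
    y: Sequence[float],
    config: GaConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> GaResult:
    """Evolve a feature panel minimizing PLS RMSECV.

    Stops early once the fraction of the population identical to the elite
    chromosome reaches ``convergence_fraction``.
    """
    config = config or GaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ModelError("need at least 2 features to select from")
    if np.unique(y).size < 2:
        raise ModelError("both classes must be present")
    feature_ids = list(feature_ids) if feature_ids is not None else [str(i) for i in range(p)]

    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}

    pop = rng.random((config.population_size, p)) < config.initial_inclusion_prob
    for chrom in pop:  # guarantee non-empty chromosomes at start
        if not chrom.any():
            chrom[rng.integers(p)] = True

    fitness = np.array([_fitness(X, y, c, config, cache) for c in pop])
    best_idx = int(np.argmin(fitness))
    elite, elite_fit = pop[best_idx].copy(), float(fitness[best_idx])
    trace = [elite_fit]
    gen = 0

    for gen in range(1, config.max_generations + 1):
        children = []
        while len(children) < config.population_size:
            # tournament of 2 for each parent
            idx = rng.integers(config.population_size, size=4)
            pa = pop[idx[0]] if fitness[idx[0]] <= fitness[idx[1]] else pop[idx[1]]
            pb = pop[idx[2]] if fitness[idx[2]] <= fitness[idx[3]] else pop[idx[3]]
            ca, cb = _crossover(pa, pb, config.crossover, rng)
            children.extend([ca, cb])
        pop = np.array(children[: config.population_size])
        flips = rng.random(pop.shape) < config.mutation_rate
        pop ^= flips
        pop[0] = elite  # elitism
        fitness = np.array([_fitness(X, y, c, config, cache) for c in pop])
        best_idx = int(np.argmin(fitness))
        if fitness[best_idx] < elite_fit:
            elite, elite_fit = pop[best_idx].copy(), float(fitness[best_idx])
        trace.append(elite_fit)
        same = np.mean([(c == elite).all() for c in pop])
        if same >= config.convergence_fraction:
            break

    return GaResult(
        selected=[f for f, m in zip(feature_ids, elite) if m],
        selected_mask=elite,
        best_rmsecv=elite_fit,
        fitness_trace=trace,
        generations_run=gen,
        config=config,
    )
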