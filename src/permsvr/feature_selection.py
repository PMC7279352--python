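"""Descriptor-subset selection: genetic search (GFA) and recursive
feature elimination (RFE).

The genetic search explores size-bounded descriptor subsets encoded as
membership masks, scored by the cross-validated RMSE of a fixed
moderate-hyperparameter RBF SVR (model selection is deliberately separated
from hyperparameter tuning, which happens later on the grid).  RFE then
trims a subset by repeatedly discarding the descriptor whose removal least
degrades — or most improves — the cross-validated RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CompoundTable
from .svr import DEFAULT_C, DEFAULT_EPSILON, SVRSpec, cv_rmse

__all__ = ["GFAConfig", "SubsetCandidate", "gfa_select", "rfe_select"]


@dataclass(frozen=True)
class GFAConfig:
    """Genetic-search settings.

    Tournament selection (size 3), uniform crossover on membership masks,
    per-gene mutation, subsets constrained to [subset_min, subset_max]
    descriptors.
    """

    population: int = 50
    generations: int = 100
    subset_min: int = 3
    subset_max: int = 6
    mutation_rate: float = 0.1
    tournament: int = 3
    cv_folds: int = 5
    elite_size: int = 10


@dataclass(frozen=True)
class SubsetCandidate:
    """One candidate descriptor subset with its cross-validated fitness."""

    names: tuple[str, ...]
    fitness: float              # CV-RMSE, log10 units (lower is better)
    generation: int


def _default_fitness_spec(subset: tuple[str, ...], n_desc: int) -> SVRSpec:
    # fixed moderate hyperparameters; gamma ~ 1/d on autoscaled descriptors
    return SVRSpec(
        "epsilon",
        C=DEFAULT_C,
        gamma=1.0 / max(len(subset), 1),
        epsilon=DEFAULT_EPSILON,
        subset=subset,
    )


def _subset_fitness(
    train: CompoundTable,
    response: np.ndarray,
    subset: tuple[str, ...],
    cv_folds: int,
    seed: int,
    cache: dict,
) -> float:
    if subset not in cache:
        spec = _default_fitness_spec(subset, len(train.descriptor_names))
        cache[subset] = cv_rmse(train, response, spec, cv_folds=cv_folds, seed=seed)
    return cache[subset]


def _repair(mask: np.ndarray, rng: np.random.Generator, lo: int, hi: int) -> np.ndarray:
    """Force a membership mask into the [lo, hi] size window."""
    mask = mask.copy()
    on = np.flatnonzero(mask)
    off = np.flatnonzero(~mask)
    if len(on) > hi:
        drop = rng.choice(on, size=len(on) - hi, replace=False)
        mask[drop] = False
    elif len(on) < lo:
        add = rng.choice(off, size=lo - len(on), replace=False)
        mask[add] = True
    return mask


def gfa_select(
    train: CompoundTable,
    response: np.ndarray,
    config: GFAConfig | None = None,
    seed: int = 0,
) -> list[SubsetCandidate]:
    """Genetic search over descriptor subsets; returns the elite archive.

    The archive holds the best distinct subsets ever seen, sorted by
    fitness (CV-RMSE ascending, ties by subset then names for a total
    order).  Fully deterministic under a fixed seed.
    """
    cfg = config or GFAConfig()
    names = train.descriptor_names
    d = len(names)
    if cfg.subset_max > d:
        raise ValueError(f"subset_max={cfg.subset_max} exceeds descriptor count {d}")
    if cfg.subset_min < 1 or cfg.subset_min > cfg.subset_max:
        raise ValueError("invalid subset size bounds")
    y = np.asarray(response, dtype=float)
    rng = np.random.default_rng(seed)
    cache: dict[tuple[str, ...], float] = {}

    def mask_to_subset(mask: np.ndarray) -> tuple[str, ...]:
        return tuple(names[i] for i in np.flatnonzero(mask))

    def fitness(mask: np.ndarray) -> float:
        return _subset_fitness(train, y, mask_to_subset(mask), cfg.cv_folds, seed, cache)

    # initial population: random masks within the size window
    pop = []
    for _ in range(cfg.population):
        size = rng.integers(cfg.subset_min, cfg.subset_max + 1)
        mask = np.zeros(d, dtype=bool)
        mask[rng.choice(d, size=size, replace=False)] = True
        pop.append(mask)

    archive: dict[tuple[str, ...], SubsetCandidate] = {}

    def record(mask: np.ndarray, gen: int) -> float:
        sub = mask_to_subset(mask)
        fit = fitness(mask)
        if sub not in archive:
            archive[sub] = SubsetCandidate(sub, fit, gen)
        return fit

    fits = [record(m, 0) for m in pop]
    for gen in range(1, cfg.generations + 1):
        children = []
        while len(children) < cfg.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, size=cfg.tournament)
                best = min(contenders, key=lambda i: fits[i])
                parents.append(pop[best])
            # uniform crossover + mutation on the membership mask
            take = rng.random(d) < 0.5
            child = np.where(take, parents[0], parents[1])
            flip = rng.random(d) < cfg.mutation_rate
            child = child ^ flip
            children.append(_repair(child, rng, cfg.subset_min, cfg.subset_max))
        pop = children
        fits = [record(m, gen) for m in pop]

    ranked = sorted(archive.values(), key=lambda c: (c.fitness, len(c.names), c.names))
    return ranked[: cfg.elite_size]


def rfe_select(
    train: CompoundTable,
    response: np.ndarray,
    subset: list[str] | tuple[str, ...],
    tolerance: float = 0.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[str, ...]:
    """Recursive feature elimination on one descriptor subset.

    Repeatedly refits with each descriptor left out; the descriptor whose
    removal least degrades (or most improves) the cross-validated RMSE is
    discarded, as the one with the smallest contribution.  Stops when the
    best removal would degrade the RMSE by more than ``tolerance`` or when
    a single descriptor remains.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    current = tuple(subset)
    if len(current) < 2:
        raise ValueError("need at least two descriptors for elimination")
    missing = [c for c in current if c not in train.descriptor_names]
    if missing:
        raise KeyError(f"subset member(s) not in table: {missing}")
    y = np.asarray(response, dtype=float)
    cache: dict[tuple[str, ...], float] = {}

    base = _subset_fitness(train, y, current, cv_folds, seed, cache)
    while len(current) > 1:
        trials = []
        for victim in current:
            reduced = tuple(c for c in current if c != victim)
            trials.append(
                (_subset_fitness(train, y, reduced, cv_folds, seed, cache), victim, reduced)
            )
        trials.sort(key=lambda t: (t[0], current.index(t[1])))
        best_rmse, _, best_reduced = trials[0]
        if best_rmse - base > tolerance:
            break
        current, base = best_reduced, best_rmse
    return current
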