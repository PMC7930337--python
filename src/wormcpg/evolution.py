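"""Two-stage real-valued genetic algorithm over the 44-parameter space.

Stage 1 evolves an isolated 7-neuron unit to produce a rhythmic B-class
pattern (fitness F1); runs crossing the 0.99 threshold seed stage 2,
where the full embodied model is evolved to crawl at the worm's speed
(fitness F1*F2). Genotypes live in the normalized [-1, 1] cube.

Operator choices (population 96, rank-based selection, uniform
recombination with probability 0.5, per-slot Gaussian mutation reflected
at the bounds, elitism 1) are disclosed defaults of this package; they
are conventional for real-valued evolutionary searches of CTRNN
parameters.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .circuit import GENOTYPE_LENGTH, Genotype
from .fitness import FitnessConstants, fitness_f1, fitness_f2
from .simulation import Masks, SimConfig, run_embodied, run_isolated_unit

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GAConfig:
    population_size: int = 96
    generations: int = 100
    mutation_sigma: float = 0.1
    mutation_prob: float = 0.25       # per-slot probability of Gaussian mutation
    recombination_prob: float = 0.5
    selection_pressure: float = 1.8    # linear-ranking pressure in [1, 2]
    elitism: int = 1
    seed: int = 0
    stage: int = 1
    stage1_threshold: float = 0.99
    stop_at_threshold: bool = True     # stop a run once best fitness passes the threshold

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 individuals")
        if not (0 < self.stage1_threshold <= 1):
            raise ValueError("stage-1 threshold must lie in (0, 1]")
        if not (1.0 <= self.selection_pressure <= 2.0):
            raise ValueError("selection pressure must lie in [1, 2]")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


@dataclasses.dataclass
class GAResult:
    best_vector: np.ndarray
    best_fitness: float
    history: pd.DataFrame              # columns: generation, best, mean
    population: np.ndarray             # final population (pop, n_params)
    fitnesses: np.ndarray              # final fitness per individual
    evaluations: int

    @property
    def best_genotype(self) -> Genotype:
        """Best individual as a named-slot genotype (44-parameter runs)."""
        return Genotype(self.best_vector)


def _ranking_probabilities(n: int, pressure: float) -> np.ndarray:
    # rank 0 = worst, rank n-1 = best
    ranks = np.arange(n, dtype=float)
    return (2.0 - pressure) / n + 2.0 * ranks * (pressure - 1.0) / (n * (n - 1.0))


def _reflect(values: np.ndarray, lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """Reflect out-of-range values back into [lo, hi]."""
    span = hi - lo
    v = np.mod(values - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


def ga_run(
    fitness_fn,
    ga_config: GAConfig,
    n_params: int = GENOTYPE_LENGTH,
    init_population: np.ndarray | None = None,
    threshold: float | None = None,
    on_generation=None,
) -> GAResult:
    """Seeded, reproducible evolutionary run maximizing ``fitness_fn``.

    ``fitness_fn(vector) -> float``; an individual whose evaluation
    raises is scored 0 and the exception logged. ``init_population``
    (if given) seeds the first generation, e.g. with a stage-1 winner.
    ``on_generation(generation, population, fitnesses)`` is called after
    every generation (checkpointing, progress logging).
    """
    cfg = ga_config
    rng = np.random.default_rng(cfg.seed)
    pop = rng.uniform(-1.0, 1.0, size=(cfg.population_size, n_params))
    if init_population is not None:
        seeded = np.atleast_2d(np.asarray(init_population, dtype=float))
        k = min(len(seeded), cfg.population_size)
        pop[:k] = seeded[:k]

    def evaluate(vec: np.ndarray) -> float:
        try:
            f = float(fitness_fn(vec))
            return f if np.isfinite(f) else 0.0
        except Exception:
            logger.exception("fitness evaluation failed; individual scored 0")
            return 0.0

    fits = np.array([evaluate(v) for v in pop])
    n_eval = len(pop)
    history = [(0, float(fits.max()), float(fits.mean()))]
    if on_generation is not None:
        on_generation(0, pop, fits)
    stop = threshold if threshold is not None else (
        cfg.stage1_threshold if cfg.stop_at_threshold else None
    )

    gen = 0
    for gen in range(1, cfg.generations + 1):
        if stop is not None and fits.max() > stop:
            break
        order = np.argsort(fits)  # ascending; last = best
        probs = _ranking_probabilities(len(pop), cfg.selection_pressure)
        new_pop = np.empty_like(pop)
        n_elite = min(cfg.elitism, len(pop))
        for e in range(n_elite):
            new_pop[e] = pop[order[-1 - e]]
        for i in range(n_elite, len(pop)):
            pa, pb = rng.choice(order, size=2, p=probs)
            child = pop[pa].copy()
            if rng.random() < cfg.recombination_prob:
                swap = rng.random(n_params) < 0.5
                child[swap] = pop[pb][swap]
            mutate = rng.random(n_params) < cfg.mutation_prob
            child[mutate] += rng.normal(0.0, cfg.mutation_sigma, size=mutate.sum())
            new_pop[i] = _reflect(child)
        new_fits = np.array([evaluate(v) for v in new_pop])
        # elites keep their known fitness (deterministic evaluations)
        for e in range(n_elite):
            new_fits[e] = fits[order[-1 - e]]
        n_eval += len(pop) - n_elite
        pop, fits = new_pop, new_fits
        history.append((gen, float(fits.max()), float(fits.mean())))
        if on_generation is not None:
            on_generation(gen, pop, fits)

    best = int(np.argmax(fits))
    return GAResult(
        best_vector=pop[best].copy(),
        best_fitness=float(fits[best]),
        history=pd.DataFrame(history, columns=["generation", "best", "mean"]),
        population=pop,
        fitnesses=fits,
        evaluations=n_eval,
    )


def stage1_fitness(
    vector: np.ndarray,
    sim_config: SimConfig | None = None,
    constants: FitnessConstants | None = None,
) -> float:
    """F1 of the isolated unit's DB and VB outputs, post-transient."""
    cfg = sim_config or SimConfig()
    trace = run_isolated_unit(vector, cfg).post_transient()
    return fitness_f1(
        {"DB": trace.neuron(0, "DB"), "VB": trace.neuron(0, "VB")},
        trace.dt, constants,
    )


def embodied_f1(trace, constants: FitnessConstants | None = None) -> float:
    """Mean over units of the per-unit B-class rhythmic-pattern fitness."""
    vals = [
        fitness_f1({"DB": trace.neuron(u, "DB"), "VB": trace.neuron(u, "VB")},
                   trace.dt, constants)
        for u in range(trace.n_units)
    ]
    return float(np.mean(vals))


def stage2_fitness(
    vector: np.ndarray,
    sim_config: SimConfig | None = None,
    constants: FitnessConstants | None = None,
    masks: Masks | None = None,
) -> float:
    """F1 * F2 of the embodied model over the post-transient window."""
    cfg = sim_config or SimConfig(duration=24.0, transient=4.0)
    trace = run_embodied(vector, cfg, masks=masks).post_transient()
    f1 = embodied_f1(trace, constants)
    f2 = fitness_f2(trace.com, trace.dt, constants)
    return f1 * f2


#: Default evaluation windows. GA evaluations use shorter simulations than
#: the final characterization runs; the stage-1 window still spans ~9 bending
#: cycles after a 2 s transient, enough for stable frequency and amplitude
#: estimates, and winners are always re-scored on the full-length protocol.
STAGE1_EVAL = SimConfig(duration=22.0, transient=2.0)
STAGE2_EVAL = SimConfig(duration=24.0, transient=4.0)


def evolve_stage1(
    ga_config: GAConfig | None = None,
    sim_config: SimConfig | None = None,
    on_generation=None,
) -> GAResult:
    cfg = ga_config or GAConfig(stage=1, population_size=64)
    sim = sim_config or STAGE1_EVAL
    return ga_run(lambda v: stage1_fitness(v, sim), cfg, on_generation=on_generation)


def evolve_stage2(
    seed_genotype: Genotype | np.ndarray,
    ga_config: GAConfig | None = None,
    sim_config: SimConfig | None = None,
    on_generation=None,
) -> GAResult:
    """Stage 2: population seeded from a stage-1 winner and its mutants."""
    cfg = ga_config or GAConfig(stage=2, stop_at_threshold=False)
    sim = sim_config or STAGE2_EVAL
    seed_vec = seed_genotype.values if isinstance(seed_genotype, Genotype) else np.asarray(seed_genotype)
    rng = np.random.default_rng(cfg.seed + 1)
    seeds = np.repeat(seed_vec[None, :], cfg.population_size, axis=0)
    seeds[1:] = _reflect(seeds[1:] + rng.normal(0.0, cfg.mutation_sigma, size=seeds[1:].shape))
    return ga_run(lambda v: stage2_fitness(v, sim), cfg, init_population=seeds,
                  threshold=None if not cfg.stop_at_threshold else cfg.stage1_threshold,
                  on_generation=on_generation)
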