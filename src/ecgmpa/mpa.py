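"""Marine Predator Algorithm (MPA) for bounded continuous minimization.

The MPA is a population metaheuristic modeled on the foraging of ocean
predators.  A population of ``n`` candidate solutions ("prey") moves
through a box-bounded search space under three successive regimes over
``tmax`` iterations:

1. *Exploration* (first third): prey take Brownian (Gaussian) steps
   relative to the elite — the best solution found so far, replicated
   across the population.
2. *Transition* (middle third): the first half of the population takes
   heavy-tailed Lévy steps (exploration) while the second half performs
   Brownian exploitation around the elite, damped by the adaptive
   factor ``CF = (1 - t/tmax)^(2 t/tmax)``.
3. *Exploitation* (last third): all prey take CF-damped Lévy steps
   around the elite.

Two further mechanisms complete the algorithm: *memory saving* (each
row keeps its best-so-far position, making the reported best fitness
monotone) and the *FADs effect* (fish-aggregating devices): occasional
randomized long jumps that prevent stagnation.

Everything here is independent of the ECG pipeline: any callable
mapping a position vector to a finite scalar can be optimized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds: ``lower`` and ``upper`` vectors of dimension d."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1 or lower.size < 1:
            raise ValueError("bounds must be equal-length 1-D vectors")
        if (lower > upper).any():
            raise ValueError("lower bounds must not exceed upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lower, self.upper)


@dataclass
class MPAParams:
    """Optimizer settings.

    ``p_const`` is the step constant P = 0.5 and ``levy_exponent`` the
    stability index of the Lévy flights (1.5), both per the original MPA
    convention, as are the population size, iteration count, FADs
    probability 0.2 and the 0.05 multiplier applied to Lévy steps inside
    the position updates.  ``phase1`` selects the exploration-phase step
    distribution: ``"brownian"`` (default, the original formulation) or
    ``"levy"``.  ``fads_pairwise`` enables the pairwise-difference jump
    applied to rows that escape the FADs long jump.
    """

    n: int = 20
    tmax: int = 50
    p_const: float = 0.5
    fads: float = 0.2
    levy_exponent: float = 1.5
    seed: int = 0
    levy_multiplier: float = 0.05
    phase1: str = "brownian"
    fads_pairwise: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if self.p_const <= 0:
            raise ValueError("P must be positive")
        if not 0.0 <= self.fads <= 1.0:
            raise ValueError("FADs probability must lie in [0, 1]")
        if self.phase1 not in ("brownian", "levy"):
            raise ValueError("phase1 must be 'brownian' or 'levy'")


@dataclass
class EliteMemory:
    """Best-so-far archive: per-row best positions and the top predator."""

    positions: np.ndarray  # n x d archived best position per row
    fitness: np.ndarray  # n archived best fitness per row
    top_position: np.ndarray
    top_fitness: float

    @property
    def elite_matrix(self) -> np.ndarray:
        """Top predator replicated across the population (the matrix E)."""
        return np.tile(self.top_position, (len(self.fitness), 1))


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best fitness after each iteration, non-increasing
    evaluations: int


def initialize(space: SearchSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform initial population: ``lower + u * (upper - lower)``."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    u = rng.uniform(size=(n, space.dim))
    return space.lower + u * (space.upper - space.lower)


def compute_cf(t: float, tmax: float) -> float:
    """Adaptive step damping ``CF = (1 - t/tmax)^(2 t/tmax)``.

    CF is 1 at t=0 (the 0**0 convention), 0.5 at t=tmax/2 and 0 at
    t=tmax.
    """
    if not 0 <= t <= tmax:
        raise ValueError(f"t must lie in [0, tmax], got t={t}, tmax={tmax}")
    frac = t / tmax
    if frac == 0.0:
        return 1.0
    return (1.0 - frac) ** (2.0 * frac)


def brownian_steps(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Standard-normal step matrix (Brownian motion increments)."""
    return rng.standard_normal(shape)


def levy_steps(
    shape: tuple[int, ...], exponent: float = 1.5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Lévy-stable step matrix via the Mantegna algorithm.

    Draws ``u / |v|^(1/beta)`` with ``u ~ N(0, sigma_u^2)`` and
    ``v ~ N(0, 1)``, which approximates a symmetric stable law with
    stability index ``beta`` — heavy-tailed jumps.
    """
    if rng is None:
        rng = np.random.default_rng()
    beta = exponent
    sigma_u = (
        math.gamma(1 + beta)
        * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.standard_normal(shape) * sigma_u
    v = rng.standard_normal(shape)
    return u / np.abs(v) ** (1 / beta)


def phase_update(
    pop: np.ndarray,
    elite: np.ndarray,
    t: int,
    tmax: int,
    params: MPAParams,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """One position update of the whole population for iteration ``t``.

    Phase boundaries: t < tmax/3 exploration; tmax/3 <= t < 2 tmax/3
    mixed (first ceil(n/2) rows Lévy, rest Brownian exploitation);
    t >= 2 tmax/3 Lévy exploitation.  All rows are clipped back into the
    box.
    """
    n, d = pop.shape
    p = params.p_const
    cf = compute_cf(t, tmax)
    new = pop.copy()
    if t < tmax / 3:
        if params.phase1 == "brownian":
            r_step = brownian_steps((n, d), rng)
        else:
            r_step = params.levy_multiplier * levy_steps(
                (n, d), params.levy_exponent, rng
            )
        step = r_step * (elite - r_step * pop)
        new = pop + p * rng.uniform(size=(n, d)) * step
    elif t < 2 * tmax / 3:
        n_levy = math.ceil(n / 2)
        rl = params.levy_multiplier * levy_steps(
            (n_levy, d), params.levy_exponent, rng
        )
        step = rl * (elite[:n_levy] - rl * pop[:n_levy])
        new[:n_levy] = pop[:n_levy] + p * rng.uniform(size=(n_levy, d)) * step
        rb = brownian_steps((n - n_levy, d), rng)
        step = rb * (rb * elite[n_levy:] - pop[n_levy:])
        new[n_levy:] = elite[n_levy:] + p * cf * step
    else:
        rl = params.levy_multiplier * levy_steps((n, d), params.levy_exponent, rng)
        step = rl * (rl * elite - pop)
        new = elite + p * cf * step
    return space.clip(new)


def memory_save(
    pop: np.ndarray, fitness: np.ndarray, memory: EliteMemory | None
) -> tuple[np.ndarray, EliteMemory]:
    """Restore each row's archived position if strictly better; update top.

    Returns the (possibly partially restored) population and the updated
    archive.  Ties keep the archive and the current row.
    """
    fitness = np.asarray(fitness, dtype=float)
    if memory is None:
        best = int(np.argmin(fitness))
        memory = EliteMemory(
            positions=pop.copy(),
            fitness=fitness.copy(),
            top_position=pop[best].copy(),
            top_fitness=float(fitness[best]),
        )
        return pop, memory
    restore = memory.fitness < fitness  # strict: archived strictly better wins
    pop = pop.copy()
    pop[restore] = memory.positions[restore]
    improved = fitness < memory.fitness
    memory.positions[improved] = pop[improved]
    memory.fitness[improved] = fitness[improved]
    best = int(np.argmin(memory.fitness))
    if memory.fitness[best] < memory.top_fitness:
        memory.top_fitness = float(memory.fitness[best])
        memory.top_position = memory.positions[best].copy()
    return pop, memory


def fads_perturb(
    pop: np.ndarray,
    t: int,
    tmax: int,
    space: SearchSpace,
    params: MPAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fish-aggregating-device effect: occasional long jumps.

    With probability ``params.fads`` per row, the row takes a long jump
    ``CF * (lower + u * (upper - lower)) * B`` with a random binary mask
    B; otherwise (when ``fads_pairwise``) it takes a pairwise-difference
    jump ``(fads (1 - r) + r) * (row_p1 - row_p2)`` with r uniform and
    p1, p2 random permutations of the population.
    """
    n, d = pop.shape
    cf = compute_cf(t, tmax)
    new = pop.copy()
    jump = rng.uniform(size=n) < params.fads
    u = rng.uniform(size=(n, d))
    mask = rng.uniform(size=(n, d)) < params.fads
    long_jump = cf * (space.lower + u * (space.upper - space.lower)) * mask
    new[jump] += long_jump[jump]
    if params.fads_pairwise:
        r = rng.uniform()
        p1 = rng.permutation(n)
        p2 = rng.permutation(n)
        pair_jump = (params.fads * (1 - r) + r) * (pop[p1] - pop[p2])
        new[~jump] += pair_jump[~jump]
    return space.clip(new)


def _evaluate(objective: Objective, pop: np.ndarray) -> np.ndarray:
    fitness = np.empty(len(pop))
    for i, row in enumerate(pop):
        val = float(objective(row))
        if not np.isfinite(val):
            raise ValueError(
                f"objective returned non-finite value {val!r} at position {row.tolist()}"
            )
        fitness[i] = val
    return fitness


def optimize(
    objective: Objective, space: SearchSpace, params: MPAParams | None = None
) -> OptimizationResult:
    """Run the full MPA loop and return the best-ever solution.

    Per iteration: evaluate, memory-save, rebuild elite, CF, phase
    update, re-evaluate, memory-save, FADs perturbation.  The trace
    holds the best fitness after each iteration and is non-increasing.
    """
    params = params or MPAParams()
    rng = np.random.default_rng(params.seed)
    pop = initialize(space, params.n, rng)
    memory: EliteMemory | None = None
    trace = np.empty(params.tmax)
    evaluations = 0
    for t in range(params.tmax):
        fitness = _evaluate(objective, pop)
        evaluations += len(pop)
        pop, memory = memory_save(pop, fitness, memory)
        elite = memory.elite_matrix
        pop = phase_update(pop, elite, t, params.tmax, params, space, rng)
        fitness = _evaluate(objective, pop)
        evaluations += len(pop)
        pop, memory = memory_save(pop, fitness, memory)
        pop = fads_perturb(pop, t, params.tmax, space, params, rng)
        trace[t] = memory.top_fitness
    return OptimizationResult(
        best_position=memory.top_position.copy(),
        best_fitness=memory.top_fitness,
        trace=trace,
        evaluations=evaluations,
    )


# Benchmark objectives for standalone testing -------------------------------


def sphere(x: np.ndarray) -> float:
    """Separable quadratic bowl, global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x**2))


def rastrigin(x: np.ndarray) -> float:
    """Highly multimodal benchmark, global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


BENCHMARKS: dict[str, Objective] = {"sphere": sphere, "rastrigin": rastrigin}
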