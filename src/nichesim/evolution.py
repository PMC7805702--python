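"""Real-valued genetic algorithm for the prey controller weights.

Generational GA with fitness-proportionate (roulette-wheel) parent
selection: N/2 parent pairs are drawn with replacement, each pair yields two
offspring by copying, two-point crossover with probability Pc, and per-gene
additive uniform mutation on [-R, R] with probability Pm.  There is no
elitism; the population is fully replaced.  Each offspring records the index
of the parent whose environment it inherits (offspring 1 of a pair matches
parent 1, offspring 2 matches parent 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GAParams:
    n: int = 40                  # population size (must be even)
    generations: int = 3000
    pc: float = 0.7              # crossover probability
    pm: float = 0.001            # per-gene mutation probability
    r: float = 0.003             # mutation half-range
    init_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self):
        if not (0.0 <= self.pc <= 1.0 and 0.0 <= self.pm <= 1.0):
            raise ValueError("pc and pm must lie in [0, 1]")
        if self.r <= 0:
            raise ValueError("mutation half-range r must be > 0")
        if self.n < 2 or self.n % 2:
            raise ValueError("population size must be even and >= 2")


def init_population(params: GAParams, genome_length: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(N, L) array of genomes, entries i.i.d. uniform on init_range."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    lo, hi = params.init_range
    return rng.uniform(lo, hi, size=(params.n, genome_length))


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportionate index draw; a flat zero wheel (reachable since
    fitness is clamped at zero) degenerates to a uniform draw."""
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be nonnegative")
    total = f.sum()
    if total == 0.0:
        return int(rng.integers(f.shape[0]))
    u = rng.uniform(0.0, total)
    return int(np.searchsorted(np.cumsum(f), u, side="right").clip(
        0, f.shape[0] - 1))


def crossover_pair(g1: np.ndarray, g2: np.ndarray, pc: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two-point crossover between copies of the two genomes.

    With probability ``pc``, cut points 0 <= a < b <= L are drawn uniformly
    over distinct positions and the half-open segment [a, b) is swapped
    between the copies; otherwise verbatim copies are returned.  Parents are
    never modified.
    """
    if g1.shape != g2.shape:
        raise ValueError("genome length mismatch")
    c1 = g1.copy()
    c2 = g2.copy()
    if rng.uniform() < pc:
        length = g1.shape[0]
        a, b = np.sort(rng.choice(length + 1, size=2, replace=False))
        c1[a:b], c2[a:b] = g2[a:b].copy(), g1[a:b].copy()
    return c1, c2


def mutate(g: np.ndarray, pm: float, r: float,
           rng: np.random.Generator) -> np.ndarray:
    """Each gene independently perturbed with probability ``pm`` by uniform
    noise on [-r, r].  Mutated values are not clamped: only initialization
    is range-bounded."""
    out = g.copy()
    mask = rng.uniform(size=g.shape[0]) < pm
    k = int(mask.sum())
    if k:
        out[mask] += rng.uniform(-r, r, size=k)
    return out


def next_generation(pop: np.ndarray, fitnesses: np.ndarray,
                    params: GAParams,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Produce the next population.

    Returns (offspring, parent_index) where ``parent_index[i]`` is the
    member of the old population whose end-of-evaluation environment
    offspring ``i`` inherits; offspring of one pair map to their respective
    parents in order.
    """
    n = params.n
    if pop.shape[0] != n or len(fitnesses) != n:
        raise ValueError("population/fitness size mismatch")
    offspring = np.empty_like(pop)
    parent_index = np.empty(n, dtype=int)
    for k in range(n // 2):
        p1 = roulette_select(fitnesses, rng)
        p2 = roulette_select(fitnesses, rng)
        c1, c2 = crossover_pair(pop[p1], pop[p2], params.pc, rng)
        offspring[2 * k] = mutate(c1, params.pm, params.r, rng)
        offspring[2 * k + 1] = mutate(c2, params.pm, params.r, rng)
        parent_index[2 * k] = p1
        parent_index[2 * k + 1] = p2
    return offspring, parent_index
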