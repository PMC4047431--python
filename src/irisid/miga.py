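"""Multi-island genetic algorithm (MIGA) for the bounded parameter search.

A bit-string GA whose population is split across islands evolving
independently (binary tournament selection with single-elite preservation,
single-point crossover, per-bit mutation); every ``migration_interval``
generations each island's best individual migrates along a ring, replacing
the destination island's worst.  Parameters are Gray-coded with
``bits_per_parameter`` bits and mapped affinely onto their bounds, which
avoids the Hamming cliffs of plain binary coding under bit mutation.

The default configuration is islands=2, generations=10, population=25,
crossover=1.0, mutation=0.01, migration rate=0.01, migration interval=5 —
a 500-evaluation budget per optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["MIGAConfig", "OptimizationTrace", "optimize",
           "encode", "decode", "DEFAULT_BOUNDS"]

#: default search box for the second-order Ogden unknowns
#: (mu1, alpha1, mu2, alpha2): mu in MPa, alpha dimensionless
DEFAULT_BOUNDS = ((0.001, 1.0), (1.0, 100.0), (0.001, 1.0), (1.0, 100.0))


@dataclass
class MIGAConfig:
    n_islands: int = 2
    n_generations: int = 10
    population_size: int = 25
    crossover_rate: float = 1.0
    mutation_rate: float = 0.01          # per bit
    migration_rate: float = 0.01
    migration_interval: int = 5          # generations
    bounds: tuple = DEFAULT_BOUNDS
    bits_per_parameter: int = 16
    seed: int = 0
    penalty: float = 1e6                 # objective value for failures
    initial_guesses: tuple = ()          # vectors planted in the population

    def __post_init__(self):
        if self.n_islands < 1 or self.population_size < 2 \
                or self.n_generations < 1:
            raise ValueError("islands, generations >= 1; population >= 2")
        for r in (self.crossover_rate, self.mutation_rate,
                  self.migration_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.migration_interval < 1:
            raise ValueError("migration interval >= 1")
        if self.bits_per_parameter < 8:
            raise ValueError("bits_per_parameter >= 8")
        for lo, hi in self.bounds:
            if not lo < hi or not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError("bounds must be finite with lo < hi")

    @property
    def n_parameters(self) -> int:
        return len(self.bounds)

    @property
    def total_evaluations(self) -> int:
        return self.n_islands * self.n_generations * self.population_size


@dataclass
class OptimizationTrace:
    """Per-evaluation history of the search."""

    records: pd.DataFrame         # generation, island, parameters, value
    best_parameters: np.ndarray
    best_value: float
    best_so_far: np.ndarray       # one entry per evaluation

    @property
    def total_evaluations(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Gray encoding
# ---------------------------------------------------------------------------

def _gray_to_int(bits: np.ndarray) -> np.ndarray:
    """Gray-coded bit block (..., nbits) -> integers (MSB first)."""
    binary = np.cumsum(bits, axis=-1) % 2      # prefix XOR
    weights = 2 ** np.arange(bits.shape[-1] - 1, -1, -1)
    return binary @ weights


def _int_to_gray(val: np.ndarray, nbits: int) -> np.ndarray:
    val = np.asarray(val)
    g = val ^ (val >> 1)
    shifts = np.arange(nbits - 1, -1, -1)
    return ((g[..., None] >> shifts) & 1).astype(np.uint8)


def decode(bits: np.ndarray, config: MIGAConfig) -> np.ndarray:
    """Bit-string -> parameter vector(s) on the configured bounds."""
    bits = np.asarray(bits, dtype=np.uint8)
    npar, nb = config.n_parameters, config.bits_per_parameter
    if bits.shape[-1] != npar * nb:
        raise ValueError(f"bit-string length must be {npar * nb}")
    blocks = bits.reshape(bits.shape[:-1] + (npar, nb))
    ints = _gray_to_int(blocks)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    return lo + ints * (hi - lo) / (2**nb - 1)


def encode(x: Sequence[float], config: MIGAConfig) -> np.ndarray:
    """Parameter vector -> Gray bit-string (inverse of decode up to the
    quantization step (hi - lo) / (2**bits - 1))."""
    x = np.asarray(x, dtype=float)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    nb = config.bits_per_parameter
    ints = np.clip(np.rint((x - lo) / (hi - lo) * (2**nb - 1)),
                   0, 2**nb - 1).astype(np.int64)
    return _int_to_gray(ints, nb).reshape(x.shape[:-1] + (-1,))


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------

def optimize(evaluate: Callable[[np.ndarray], float],
             config: MIGAConfig | None = None):
    """Minimize ``evaluate`` over the configured box.

    ``evaluate`` receives a parameter vector and returns a scalar;
    exceptions it raises are recorded as the configured penalty value and
    never abort the search.  Returns (best_parameters, best_value, trace);
    the search is bit-reproducible for a fixed seed.
    """
    cfg = config or MIGAConfig()
    rng = np.random.default_rng(cfg.seed)
    nbits = cfg.n_parameters * cfg.bits_per_parameter
    pop = rng.integers(0, 2, size=(cfg.n_islands, cfg.population_size, nbits),
                       dtype=np.uint8)
    for i, guess in enumerate(cfg.initial_guesses):
        isl, slot = i % cfg.n_islands, i // cfg.n_islands
        if slot < cfg.population_size:
            pop[isl, slot] = encode(np.asarray(guess, dtype=float), cfg)

    rows = []
    best_so_far = []
    best_val = np.inf
    best_x = None
    fitness = np.empty((cfg.n_islands, cfg.population_size))

    def run_eval(bits, gen, isl):
        nonlocal best_val, best_x
        x = decode(bits, cfg)
        try:
            v = float(evaluate(x))
            if not np.isfinite(v):
                v = cfg.penalty
        except Exception:
            v = cfg.penalty
        rows.append((gen, isl, *x, v))
        if v < best_val:
            best_val = v
            best_x = x
        best_so_far.append(best_val)
        return v

    n_migrants = max(1, round(cfg.migration_rate * cfg.population_size))
    for gen in range(1, cfg.n_generations + 1):
        for isl in range(cfg.n_islands):
            for k in range(cfg.population_size):
                fitness[isl, k] = run_eval(pop[isl, k], gen, isl)
        if gen == cfg.n_generations:
            break
        # ring migration of the islands' best individuals (before the
        # evolutionary step, so the index/fitness bookkeeping is current)
        if cfg.n_islands > 1 and gen % cfg.migration_interval == 0:
            order = np.argsort(fitness, axis=1)
            migrants = [(pop[isl, order[isl, :n_migrants]].copy(),
                         fitness[isl, order[isl, :n_migrants]].copy())
                        for isl in range(cfg.n_islands)]
            for isl in range(cfg.n_islands):
                dest = (isl + 1) % cfg.n_islands
                worst = order[dest, -n_migrants:]
                pop[dest, worst] = migrants[isl][0]
                fitness[dest, worst] = migrants[isl][1]
        # independent evolution per island
        for isl in range(cfg.n_islands):
            fit = fitness[isl]
            elite = pop[isl, np.argmin(fit)].copy()
            # binary tournament selection
            cand = rng.integers(0, cfg.population_size,
                                size=(cfg.population_size - 1, 2))
            winners = np.where(fit[cand[:, 0]] <= fit[cand[:, 1]],
                               cand[:, 0], cand[:, 1])
            children = pop[isl, winners].copy()
            # single-point crossover on consecutive pairs
            for a in range(0, len(children) - 1, 2):
                if rng.random() < cfg.crossover_rate:
                    cut = rng.integers(1, nbits)
                    tail = children[a, cut:].copy()
                    children[a, cut:] = children[a + 1, cut:]
                    children[a + 1, cut:] = tail
            # per-bit mutation
            if cfg.mutation_rate > 0:
                flips = rng.random(children.shape) < cfg.mutation_rate
                children[flips] ^= 1
            pop[isl, 0] = elite
            pop[isl, 1:] = children

    cols = (["generation", "island"]
            + [f"x{i}" for i in range(cfg.n_parameters)] + ["value"])
    trace = OptimizationTrace(
        records=pd.DataFrame(rows, columns=cols),
        best_parameters=np.asarray(best_x),
        best_value=best_val,
        best_so_far=np.asarray(best_so_far))
    return trace.best_parameters, trace.best_value, trace
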