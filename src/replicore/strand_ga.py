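"""Genetic algorithm with semiconservative, strand-asymmetric replication.

Each genome is a binary inclusion vector for a 0/1 knapsack instance. Every
surviving genome replicates into two daughters per generation through two
copy channels with independent per-bit flip rates: ``mu_leading`` (the
high-fidelity leading-strand copy) and ``mu_lagging`` (the error-prone
lagging-strand copy). Parity mutagenesis is ``mu_leading == mu_lagging``;
disparity is ``mu_leading < mu_lagging``. The "total mutation rate" of a run
is the per-bit rate averaged over the two daughters,
``(mu_leading + mu_lagging) / 2``, so parity at 4% means both channels at
0.04 and pure disparity at 4% means ``(0, 0.08)``.

Selection is truncation: the 2N daughters are ranked by fitness (stable sort,
ties broken by parent index then leading-before-lagging) and the top N kept.
With ``mu_leading = 0`` the best genome's faithful daughter always survives
truncation, so best fitness is monotone non-decreasing — the "guarantee of
principal" that lets disparity runs tolerate per-genome mutation numbers far
beyond the parity error threshold.

Infeasible (overweight) genomes score 0; a run is extinct when the feasible
fraction has been 0 for 10 consecutive generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnapsackInstance",
    "GAParams",
    "GARunResult",
    "generate_instance",
    "fitness",
    "replicate_semiconservative",
    "dp_optimum",
    "run",
]

DP_CELL_BUDGET = 10**7
EXTINCTION_WINDOW = 10


@dataclass(frozen=True)
class KnapsackInstance:
    """0/1 knapsack: positive integer weights/values and a capacity.

    Genomes are binary inclusion vectors; taking an object twice is not
    representable by construction.
    """

    weights: tuple[int, ...]
    values: tuple[int, ...]
    capacity: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.values):
            raise ValueError("weights and values must have equal length")
        if any(w <= 0 for w in self.weights) or any(v <= 0 for v in self.values):
            raise ValueError("weights and values must be positive integers")
        if self.capacity < 0:
            raise ValueError("capacity must be non-negative")

    @property
    def n_items(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class GAParams:
    """Run parameters; ``mode`` is derived from the two channel rates."""

    population_size: int = 200
    generations: int = 500
    mu_leading: float = 0.0
    mu_lagging: float = 0.08
    keep_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2 != 0:
            raise ValueError(
                f"population_size must be an even integer >= 2, got {self.population_size}"
            )
        for name in ("mu_leading", "mu_lagging"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError(f"keep_fraction must be in (0, 1], got {self.keep_fraction}")

    @property
    def mode(self) -> str:
        return "parity" if self.mu_leading == self.mu_lagging else "disparity"

    @property
    def total_rate(self) -> float:
        """Per-bit mutation rate averaged over the two daughters."""
        return 0.5 * (self.mu_leading + self.mu_lagging)


@dataclass
class GARunResult:
    """Per-generation trajectory plus end-state flags."""

    best: np.ndarray
    mean: np.ndarray
    feasible_fraction: np.ndarray
    dp_opt: int
    solved: bool
    extinct: bool
    generation_solved: int | None
    params: GAParams = field(repr=False, default=None)  # type: ignore[assignment]

    def trajectory_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best)),
                "best": self.best,
                "mean": self.mean,
                "feasible_fraction": self.feasible_fraction,
            }
        )


def generate_instance(
    n_items: int,
    seed: int,
    weight_range: tuple[int, int] = (1, 100),
    value_range: tuple[int, int] = (1, 100),
    capacity_fraction: float = 0.5,
) -> KnapsackInstance:
    """Random knapsack instance: weights and values uniform on the given
    ranges, capacity a fixed fraction of the total weight. Deterministic
    given ``seed``."""
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    for name, (lo, hi) in (("weight_range", weight_range), ("value_range", value_range)):
        if lo < 1 or hi < lo:
            raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got {(lo, hi)}")
    if not 0.0 < capacity_fraction <= 1.0:
        raise ValueError(f"capacity_fraction must be in (0, 1], got {capacity_fraction}")
    rng = np.random.default_rng(seed)
    weights = rng.integers(weight_range[0], weight_range[1] + 1, size=n_items)
    values = rng.integers(value_range[0], value_range[1] + 1, size=n_items)
    capacity = round(capacity_fraction * int(weights.sum()))
    return KnapsackInstance(
        weights=tuple(int(w) for w in weights),
        values=tuple(int(v) for v in values),
        capacity=capacity,
        seed=seed,
    )


def fitness(genome: np.ndarray, instance: KnapsackInstance) -> int:
    """Total value of selected items, or 0 if the weight limit is exceeded."""
    bits = np.asarray(genome)
    if bits.shape != (instance.n_items,):
        raise ValueError(
            f"genome length {bits.shape} does not match instance n_items={instance.n_items}"
        )
    w = int(bits @ np.asarray(instance.weights))
    if w > instance.capacity:
        return 0
    return int(bits @ np.asarray(instance.values))


def _population_fitness(
    pop: np.ndarray, instance: KnapsackInstance
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness vector and feasibility mask (weight within capacity)."""
    w = pop @ np.asarray(instance.weights)
    v = pop @ np.asarray(instance.values)
    feasible = w <= instance.capacity
    return np.where(feasible, v, 0), feasible


def replicate_semiconservative(
    genome: np.ndarray,
    mu_leading: float,
    mu_lagging: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One semiconservative replication: each daughter is the parent with
    every bit independently flipped at its channel's rate."""
    bits = np.asarray(genome, dtype=np.uint8)
    lead = bits ^ (rng.random(bits.shape) < mu_leading)
    lag = bits ^ (rng.random(bits.shape) < mu_lagging)
    return lead.astype(np.uint8), lag.astype(np.uint8)


def dp_optimum(instance: KnapsackInstance, cell_budget: int = DP_CELL_BUDGET) -> int:
    """Exact 0/1-knapsack optimum by dynamic programming over capacity."""
    cells = instance.n_items * (instance.capacity + 1)
    if cells > cell_budget:
        raise ValueError(
            f"DP table of {cells} cells exceeds budget {cell_budget} "
            f"(n_items={instance.n_items}, capacity={instance.capacity})"
        )
    dp = np.zeros(instance.capacity + 1, dtype=np.int64)
    for w, v in zip(instance.weights, instance.values):
        if w <= instance.capacity:
            np.maximum(dp[w:], dp[:-w] + v, out=dp[w:])
    return int(dp[-1])


def run(
    instance: KnapsackInstance,
    params: GAParams,
    founders: np.ndarray | None = None,
) -> GARunResult:
    """Run the generational loop.

    Each generation every genome produces a leading and a lagging daughter;
    truncation keeps the top ``keep_fraction`` of the 2N daughters (at most
    N), with ties broken by (fitness desc, parent index, leading before
    lagging) for bit-reproducibility. Stops early when extinct (feasible
    fraction 0 for 10 consecutive generations). ``founders`` seeds the
    initial population (a single genome is tiled to N copies); the default
    founder is the empty knapsack.
    """
    rng = np.random.default_rng(params.seed)
    N = params.population_size
    n = instance.n_items
    opt = dp_optimum(instance)

    if founders is None:
        pop = np.zeros((N, n), dtype=np.uint8)  # empty knapsacks (feasible)
    else:
        pop = np.array(founders, dtype=np.uint8)
        if pop.ndim == 1:
            pop = np.tile(pop, (N, 1))
        if pop.shape != (N, n):
            raise ValueError(
                f"founders must have shape ({N}, {n}) or ({n},), got {pop.shape}"
            )
    best_hist, mean_hist, feas_hist = [], [], []
    solved_at: int | None = None
    zero_feasible_streak = 0
    extinct = False

    fit, feasible = _population_fitness(pop, instance)
    _record(fit, feasible, best_hist, mean_hist, feas_hist)
    if solved_at is None and best_hist[-1] == opt:
        solved_at = 0

    keep = min(N, max(2, int(round(params.keep_fraction * 2 * N))))
    for gen in range(1, params.generations + 1):
        daughters = np.empty((2 * N, n), dtype=np.uint8)
        lead = pop ^ (rng.random((N, n)) < params.mu_leading)
        lag = pop ^ (rng.random((N, n)) < params.mu_lagging)
        # interleave so index order encodes (parent, leading-before-lagging)
        daughters[0::2] = lead
        daughters[1::2] = lag

        fit, feasible = _population_fitness(daughters, instance)
        order = np.argsort(-fit, kind="stable")  # stable: index order breaks ties
        survivors = order[:keep]
        if keep < N:  # refill to N by cycling survivors (keeps N constant)
            survivors = np.resize(survivors, N)
        pop = daughters[survivors]
        fit, feasible = fit[survivors], feasible[survivors]

        _record(fit, feasible, best_hist, mean_hist, feas_hist)
        if solved_at is None and best_hist[-1] == opt:
            solved_at = gen
        if feas_hist[-1] == 0.0:
            zero_feasible_streak += 1
            if zero_feasible_streak >= EXTINCTION_WINDOW:
                extinct = True
                break
        else:
            zero_feasible_streak = 0

    return GARunResult(
        best=np.array(best_hist),
        mean=np.array(mean_hist),
        feasible_fraction=np.array(feas_hist),
        dp_opt=opt,
        solved=solved_at is not None,
        extinct=extinct,
        generation_solved=solved_at,
        params=params,
    )


def _record(
    fit: np.ndarray, feasible: np.ndarray, best: list, mean: list, feas: list
) -> None:
    best.append(int(fit.max()))
    mean.append(float(fit.mean()))
    feas.append(float(np.count_nonzero(feasible) / len(feasible)))
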