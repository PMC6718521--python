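"""Inverse design of oral glucose ingestion patterns by evolutionary programming.

The search space is the set of integer-gram patterns u = [u_0, u_5, ..., u_60]
on the 5-min grid over 0-60 min with sum(u) = 50 g and u_0 >= 1 g; each
nonzero slot becomes a 0.5-min ingestion event.  The objective J(u) is the
peak of simulated blood glucose (G_Max) or insulin (I_Max) over [0, T].

The EP loop mutates every individual by L random 1-g transfers between
slots (L decaying on a fixed schedule), scores the combined parent+child
pool by M-opponent win-count tournaments, keeps the top half, and tracks
the best pattern ever evaluated.  Crossover is deliberately absent: under
the fixed-total constraint a recombination operator is awkward, and the
1-g-transfer mutation already explores the simplex of compositions.

For small instances :func:`enumerate_patterns` provides the exact oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .model import IngestionSchedule, Subject
from .simulate import SolverSettings, peak_value, simulate

__all__ = [
    "IngestionPattern",
    "ObjectiveSpec",
    "OptimizerSettings",
    "OptimizationResult",
    "DEFAULT_SLOTS",
    "pattern_to_schedule",
    "init_population",
    "mutate_pattern",
    "evaluate_objective",
    "tournament_scores",
    "optimize",
    "enumerate_patterns",
    "pattern_count",
]

#: The 13 ingestion slots [min] of the standard search space.
DEFAULT_SLOTS = tuple(float(t) for t in range(0, 65, 5))

_EVENT_DURATION = 0.5  # min, per-slot ingestion duration


@dataclass(frozen=True)
class IngestionPattern:
    """Integer grams per slot; sum fixed, first slot at least 1 g."""

    grams: tuple[int, ...]
    slot_times: tuple[float, ...] = DEFAULT_SLOTS

    def __init__(self, grams, slot_times=DEFAULT_SLOTS):
        grams = tuple(int(v) for v in grams)
        slot_times = tuple(float(t) for t in slot_times)
        if len(grams) != len(slot_times):
            raise ValueError("grams and slot_times must have equal length")
        if any(v < 0 for v in grams):
            raise ValueError("slot grams must be nonnegative integers")
        if grams[0] < 1:
            raise ValueError("at least 1 g must be ingested at the first slot")
        object.__setattr__(self, "grams", grams)
        object.__setattr__(self, "slot_times", slot_times)

    @property
    def total(self) -> int:
        return sum(self.grams)

    @classmethod
    def bolus(cls, total: int = 50, slot_times=DEFAULT_SLOTS) -> "IngestionPattern":
        g = [0] * len(slot_times)
        g[0] = total
        return cls(g, slot_times)

    @classmethod
    def endpoint_split(cls, total: int = 50, slot_times=DEFAULT_SLOTS) -> "IngestionPattern":
        if len(slot_times) == 1:
            return cls.bolus(total, slot_times)
        g = [0] * len(slot_times)
        g[0], g[-1] = 1, total - 1
        return cls(g, slot_times)


def pattern_to_schedule(p: IngestionPattern) -> IngestionSchedule:
    """One 0.5-min event per nonzero slot; total grams preserved."""
    events = [(t, float(g), _EVENT_DURATION) for t, g in zip(p.slot_times, p.grams) if g > 0]
    return IngestionSchedule(events)


@dataclass(frozen=True)
class ObjectiveSpec:
    """What to minimize and how to simulate it.

    ``solver`` is used during the search; ``final_solver`` re-evaluates the
    winning pattern at the fine Euler step used for reported values.
    """

    target: str = "glucose_peak"  # "glucose_peak" | "insulin_peak"
    horizon: float = 480.0
    solver: SolverSettings = field(
        default_factory=lambda: SolverSettings(method="euler", step=0.01, horizon=480.0)
    )
    final_solver: SolverSettings = field(
        default_factory=lambda: SolverSettings(method="euler", step=0.001, horizon=480.0)
    )

    def __post_init__(self):
        if self.target not in ("glucose_peak", "insulin_peak"):
            raise KeyError(f"unknown objective target {self.target!r}")

    @property
    def species(self) -> str:
        return "G" if self.target == "glucose_peak" else "I"


@dataclass(frozen=True)
class OptimizerSettings:
    """EP configuration.  Desk-scale defaults; the study-scale values are
    N=500 individuals, K=500 generations, L from 20 decremented every 25
    generations, M=N/5 opponents, 5 trials."""

    pop_size: int = 100
    n_generations: int = 100
    l_initial: int = 20
    l_decrement: int = 1
    l_interval: int = 25
    tournament_m: int | None = None   # default pop_size // 5
    trials: int = 2
    seed: int = 0
    strict_transfer: bool = False     # source needs > 1 g instead of >= 1 g

    def __post_init__(self):
        if self.pop_size < 2 or self.n_generations < 1 or self.trials < 1:
            raise ValueError("pop_size >= 2, n_generations >= 1, trials >= 1 required")
        if self.l_initial < 0:
            raise ValueError("L schedule must stay nonnegative")

    @property
    def m(self) -> int:
        return self.tournament_m if self.tournament_m is not None else max(1, self.pop_size // 5)

    def l_at(self, generation: int) -> int:
        return max(0, self.l_initial - self.l_decrement * (generation // self.l_interval))


@dataclass(frozen=True)
class OptimizationResult:
    best_pattern: IngestionPattern
    best_j: float                      # objective at the final (fine) solver
    best_j_search: float               # objective at the search solver
    trace: tuple[float, ...]           # best-so-far J per generation, best trial
    trial_results: tuple[dict, ...]    # per trial: best pattern grams, J, trace
    settings: OptimizerSettings
    objective: ObjectiveSpec
    n_evaluations: int

    def pattern_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_min": self.best_pattern.slot_times, "grams": self.best_pattern.grams}
        )


def init_population(
    settings: OptimizerSettings,
    total: int,
    rng: np.random.Generator,
    slot_times=DEFAULT_SLOTS,
) -> list[IngestionPattern]:
    """Bolus seed + endpoint-split seed + random compositions.

    Random individuals place the mandatory 1 g at the first slot and
    scatter the remaining total-1 grams uniformly over all slots.
    """
    n_slots = len(slot_times)
    pop = [IngestionPattern.bolus(total, slot_times),
           IngestionPattern.endpoint_split(total, slot_times)]
    for _ in range(settings.pop_size - 2):
        g = rng.multinomial(total - 1, np.full(n_slots, 1.0 / n_slots))
        g[0] += 1
        pop.append(IngestionPattern(g, slot_times))
    return pop[: settings.pop_size]


def mutate_pattern(
    p: IngestionPattern, L: int, rng: np.random.Generator, strict: bool = False
) -> IngestionPattern:
    """L random 1-g transfers bracketed by remove/restore at slot 0.

    Exactly: subtract 1 g at the first slot; L times pick a (source,
    destination) slot pair uniformly at random and move 1 g if the source
    holds at least 1 g (strictly more than 1 g with ``strict``); add 1 g
    back at the first slot.  Total grams and the u_0 >= 1 constraint are
    preserved by construction; L = 0 returns the pattern unchanged.
    """
    g = np.array(p.grams, dtype=np.int64)
    n = g.size
    g[0] -= 1
    threshold = 1 if strict else 0
    for _ in range(L):
        src = int(rng.integers(n))
        dst = int(rng.integers(n))
        if g[src] > threshold:
            g[src] -= 1
            g[dst] += 1
    g[0] += 1
    return IngestionPattern(g, p.slot_times)


def evaluate_objective(
    p: IngestionPattern,
    subject: Subject,
    objective: ObjectiveSpec,
    final: bool = False,
) -> float:
    """J(u): the peak of G or I over [0, T] for the pattern's schedule."""
    solver = objective.final_solver if final else objective.solver
    traj = simulate(subject, pattern_to_schedule(p), solver)
    return peak_value(traj, objective.species)


def tournament_scores(
    j_values: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Win counts against m random opponents (uniform, with replacement,
    excluding self) — the number of opponents with strictly larger J."""
    j = np.asarray(j_values, dtype=float)
    n = j.size
    if n < 2:
        raise ValueError("need at least two individuals")
    opp = rng.integers(0, n - 1, size=(n, m))
    opp += opp >= np.arange(n)[:, None]
    return (j[opp] > j[:, None]).sum(axis=1)


def optimize(
    subject: Subject,
    objective: ObjectiveSpec,
    settings: OptimizerSettings,
    total: int = 50,
    slot_times=DEFAULT_SLOTS,
    evaluator: Callable[[IngestionPattern], float] | None = None,
) -> OptimizationResult:
    """Run the EP loop for the configured trials and return the best pattern.

    Objective values are memoized per pattern (the schedule->J map is
    deterministic), so repeated patterns cost nothing.  ``evaluator``
    overrides the simulation objective (used by oracle-equivalence tests
    to share one evaluation path with exhaustive enumeration).
    """
    cache: dict[tuple[int, ...], float] = {}
    n_evals = 0

    def J(p: IngestionPattern) -> float:
        nonlocal n_evals
        key = p.grams
        if key not in cache:
            n_evals += 1
            cache[key] = (
                evaluator(p) if evaluator is not None
                else evaluate_objective(p, subject, objective)
            )
        return cache[key]

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.trials)
    trial_results = []
    best_pat, best_j = None, math.inf
    for ss in seeds:
        rng = np.random.default_rng(ss)
        pop = init_population(settings, total, rng, slot_times)
        j_pop = np.array([J(p) for p in pop])
        i0 = int(np.argmin(j_pop))
        u_star, j_star = pop[i0], float(j_pop[i0])
        trace = []
        for gen in range(settings.n_generations):
            L = settings.l_at(gen)
            children = [mutate_pattern(p, L, rng, settings.strict_transfer) for p in pop]
            j_child = np.array([J(p) for p in children])
            i_min = int(np.argmin(j_child))
            if j_child[i_min] < j_star:
                u_star, j_star = children[i_min], float(j_child[i_min])
            trace.append(j_star)

            all_p = pop + children
            all_j = np.concatenate([j_pop, j_child])
            scores = tournament_scores(all_j, settings.m, rng)
            # rank by score desc; ties toward smaller J, then insertion order
            keep = np.lexsort((np.arange(all_j.size), all_j, -scores))[: settings.pop_size]
            pop = [all_p[i] for i in keep]
            j_pop = all_j[keep]
        trial_results.append(
            {"pattern": u_star.grams, "j_search": j_star, "trace": tuple(trace)}
        )
        if j_star < best_j:
            best_pat, best_j = u_star, j_star

    best_trial = min(trial_results, key=lambda t: t["j_search"])
    final_j = (
        best_j if evaluator is not None
        else evaluate_objective(best_pat, subject, objective, final=True)
    )
    return OptimizationResult(
        best_pattern=best_pat,
        best_j=float(final_j),
        best_j_search=float(best_j),
        trace=best_trial["trace"],
        trial_results=tuple(trial_results),
        settings=settings,
        objective=objective,
        n_evaluations=n_evals,
    )


def pattern_count(total: int, n_slots: int, first_min: int = 1) -> int:
    """Number of feasible patterns: compositions of total-first_min over
    n_slots slots (stars and bars)."""
    return math.comb(total - first_min + n_slots - 1, n_slots - 1)


def enumerate_patterns(
    total: int,
    slot_times=DEFAULT_SLOTS,
    first_min: int = 1,
    guard: int = 10**6,
    force: bool = False,
) -> Iterator[IngestionPattern]:
    """Exhaustively yield every feasible pattern, each exactly once.

    The exact oracle for small instances; refuses instances with more than
    ``guard`` patterns unless forced (the full 50-g/13-slot space has
    ~2.2e12 patterns and is why the EP search exists).
    """
    slot_times = tuple(float(t) for t in slot_times)
    n = len(slot_times)
    if total < first_min:
        return
    if pattern_count(total, n, first_min) > guard and not force:
        raise ValueError("instance too large to enumerate; pass force=True to override")

    def compositions(remaining: int, slots_left: int):
        if slots_left == 1:
            yield (remaining,)
            return
        for v in range(remaining + 1):
            for rest in compositions(remaining - v, slots_left - 1):
                yield (v,) + rest

    for first in range(first_min, total + 1):
        for rest in compositions(total - first, n - 1) if n > 1 else [()]:
            yield IngestionPattern((first,) + rest, slot_times)
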