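"""Repeated-game orchestration: schedules, evolutions, reference runs, sweeps.

An *evolution* is a sequence of tasks (200 by default) played by the same
group, threading the trait updates from one task into the next.  Two model
families are supported:

* the **personality model**, where boldness drives an initiator race and
  follower draws, and only the initiator learns; and
* a **reference model** without personality traits, where each agent
  independently cooperates with probability ``ŝ_i`` and — when evolution
  is enabled — every cooperator updates ``ŝ_i`` by the same reinforcement
  rule from the shared task outcome.

`run_sweep` repeats evolutions over a (λ, obstacle) grid with several
replicates per cell and aggregates the windowed summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .environment import OBSTACLE_LEVELS, SuccessTable, sample_outcome
from .errors import ConfigurationError, DomainError
from .game import (
    ROLE_COOPERATOR,
    ROLE_FREE_RIDER,
    GameParams,
    PersonalityState,
    RoleAssignment,
    TaskRecord,
    compute_payoffs,
    play_stage_game,
)

__all__ = [
    "VARIANT_PERSONALITY",
    "VARIANT_REFERENCE_FIXED",
    "VARIANT_REFERENCE_EVOLVING",
    "Schedule",
    "EvolutionRecord",
    "make_schedule",
    "draw_initial_traits",
    "run_evolution",
    "run_reference_model",
    "replicate_seed",
    "run_sweep",
]

VARIANT_PERSONALITY = "personality"
VARIANT_REFERENCE_FIXED = "reference_fixed"
VARIANT_REFERENCE_EVOLVING = "reference_evolving"

DEFAULT_N_TASKS = 200
#: Changing-difficulty layout: first 60 tasks easy, tasks 61–120 hard,
#: last 80 easy again (1-based task numbering; storage is 0-based).
CHANGING_PERIODS = (60, 60, 80)


@dataclass(frozen=True)
class Schedule:
    """One obstacle label per task."""

    obstacles: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.obstacles)


@dataclass(frozen=True)
class EvolutionRecord:
    """Full task stream of a single evolution, plus the run's provenance."""

    params: GameParams
    schedule: Schedule
    seed: int | None
    model_variant: str
    initial_traits: np.ndarray
    tasks: tuple[TaskRecord, ...]

    def __len__(self) -> int:
        return len(self.tasks)

    @property
    def has_race(self) -> bool:
        return self.model_variant == VARIANT_PERSONALITY


def _check_levels(levels: Iterable[str]) -> None:
    unknown = [lv for lv in levels if lv not in OBSTACLE_LEVELS]
    if unknown:
        raise ConfigurationError(
            f"unknown obstacle level(s) {unknown}; expected one of {OBSTACLE_LEVELS}"
        )


def make_schedule(
    spec: Mapping[str, object], n_tasks: int = DEFAULT_N_TASKS
) -> Schedule:
    """Build an obstacle schedule from a declarative spec.

    ``{"fixed": level}`` repeats one level for every task.
    ``{"changing": [easy, hard]}`` runs easy/hard/easy periods of
    60/60/80 tasks (scaled proportionally if ``n_tasks`` differs from 200).
    """
    if "fixed" in spec:
        level = str(spec["fixed"])
        _check_levels([level])
        return Schedule((level,) * n_tasks)
    if "changing" in spec:
        pair = spec["changing"]
        if not (isinstance(pair, Sequence) and len(pair) == 2):
            raise ConfigurationError(
                f"'changing' must give [easy, hard] levels, got {pair!r}"
            )
        easy, hard = str(pair[0]), str(pair[1])
        _check_levels([easy, hard])
        total = sum(CHANGING_PERIODS)
        first = round(n_tasks * CHANGING_PERIODS[0] / total)
        middle = round(n_tasks * CHANGING_PERIODS[1] / total)
        last = n_tasks - first - middle
        return Schedule((easy,) * first + (hard,) * middle + (easy,) * last)
    raise ConfigurationError(
        f"schedule spec must contain 'fixed' or 'changing', got keys {sorted(spec)}"
    )


def draw_initial_traits(n_agents: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform draws on the open unit interval."""
    traits = rng.random(n_agents)
    # rng.random covers [0, 1); redraw the measure-zero boundary cases
    while np.any((traits <= 0.0) | (traits >= 1.0)):
        bad = (traits <= 0.0) | (traits >= 1.0)
        traits[bad] = rng.random(int(bad.sum()))
    return traits


def _validate_run_inputs(
    params: GameParams, schedule: Schedule, success_table: SuccessTable
) -> None:
    missing = [
        level
        for level in dict.fromkeys(schedule.obstacles)
        if (level, 1) not in success_table.probabilities
        or (level, params.n_agents) not in success_table.probabilities
    ]
    if missing:
        raise ConfigurationError(
            f"success table does not cover scheduled level(s) {missing} "
            f"for all n_C in 1..{params.n_agents}"
        )


def run_evolution(
    params: GameParams,
    schedule: Schedule,
    success_table: SuccessTable,
    seed: int | None = None,
    initial_traits: np.ndarray | None = None,
    fast: bool = False,
) -> EvolutionRecord:
    """Play the personality model over a whole schedule.

    Identical ``(seed, params, schedule, success_table)`` reproduce the
    record exactly.  When ``initial_traits`` is omitted they are drawn
    i.i.d. uniform on (0, 1) from the same seeded stream.
    """
    _validate_run_inputs(params, schedule, success_table)
    rng = np.random.default_rng(seed)
    if initial_traits is None:
        initial_traits = draw_initial_traits(params.n_agents, rng)
    state = PersonalityState(np.asarray(initial_traits, dtype=float))
    if state.n_agents != params.n_agents:
        raise DomainError(
            f"initial_traits has length {state.n_agents}, expected {params.n_agents}"
        )
    tasks = []
    for k, obstacle in enumerate(schedule.obstacles):
        record = play_stage_game(
            state, obstacle, success_table, params, rng, task_index=k, fast=fast
        )
        tasks.append(record)
        state = record.traits_after
    return EvolutionRecord(
        params=params,
        schedule=schedule,
        seed=seed,
        model_variant=VARIANT_PERSONALITY,
        initial_traits=np.asarray(initial_traits, dtype=float),
        tasks=tuple(tasks),
    )


def run_reference_model(
    params: GameParams,
    schedule: Schedule,
    success_table: SuccessTable,
    seed: int | None = None,
    evolve: bool = False,
    initial_probs: np.ndarray | None = None,
) -> EvolutionRecord:
    """Personality-free reference: each agent cooperates with probability ŝ_i.

    There is no initiator and no decision time.  ``n_C`` may be zero, in
    which case the task fails outright.  With ``evolve=True`` every
    cooperator applies ``ŝ ← r·λ + ŝ·(1 − λ)`` after each task; without
    it the strategies never change.
    """
    from .game import update_initiator_trait  # same clamped update rule

    _validate_run_inputs(params, schedule, success_table)
    rng = np.random.default_rng(seed)
    if initial_probs is None:
        initial_probs = draw_initial_traits(params.n_agents, rng)
    state = PersonalityState(np.asarray(initial_probs, dtype=float))
    if state.n_agents != params.n_agents:
        raise DomainError(
            f"initial_probs has length {state.n_agents}, expected {params.n_agents}"
        )
    tasks = []
    for k, obstacle in enumerate(schedule.obstacles):
        u = rng.random(params.n_agents)
        is_coop = u < state.traits
        roles = tuple(
            ROLE_COOPERATOR if c else ROLE_FREE_RIDER for c in is_coop
        )
        n_coop = int(is_coop.sum())
        if n_coop == 0:
            outcome = 0
        else:
            outcome = sample_outcome(success_table, obstacle, n_coop, rng)
        payoffs = compute_payoffs(roles, outcome, params)
        if evolve:
            for i in np.flatnonzero(is_coop):
                state = update_initiator_trait(state, int(i), outcome, params)
        n_bold = int(np.sum(state.traits > params.bold_threshold))
        tasks.append(
            TaskRecord(
                task_index=k,
                obstacle=obstacle,
                role_assignment=RoleAssignment(None, None, roles),
                n_cooperators=n_coop,
                n_bold=n_bold,
                outcome=outcome,
                payoffs=payoffs,
                traits_after=state,
            )
        )
    return EvolutionRecord(
        params=params,
        schedule=schedule,
        seed=seed,
        model_variant=VARIANT_REFERENCE_EVOLVING if evolve else VARIANT_REFERENCE_FIXED,
        initial_traits=np.asarray(initial_probs, dtype=float),
        tasks=tuple(tasks),
    )


def replicate_seed(base_seed: int, update_rate: float, level: str, replicate: int) -> int:
    """Deterministic per-replicate seed for sweep cells.

    Mixes (base_seed, λ in tenths, obstacle index, replicate index)
    through a SeedSequence so that cells are independent and any subset
    of the sweep can be re-run in isolation.
    """
    level_index = OBSTACLE_LEVELS.index(level)
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(update_rate * 1000)), level_index, int(replicate)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    params: GameParams,
    update_rates: Sequence[float],
    levels: Sequence[str],
    success_table: SuccessTable,
    replicates: int = 5,
    base_seed: int = 0,
    n_tasks: int = DEFAULT_N_TASKS,
    window: int | None = None,
    fast: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated grid of evolutions over update rates × obstacle levels.

    Returns ``(runs, aggregates)``: one row per (λ, level, replicate)
    with the windowed summary statistics, and per-cell means with
    standard errors over replicates (5 replicates by default).
    """
    from .metrics import summarize_evolution

    _check_levels(levels)
    if replicates < 1:
        raise ConfigurationError(f"replicates must be >= 1, got {replicates!r}")
    rows = []
    for lam in update_rates:
        cell_params = GameParams(
            n_agents=params.n_agents,
            benefit=params.benefit,
            cost=params.cost,
            update_rate=float(lam),
            bold_threshold=params.bold_threshold,
            shy_threshold=params.shy_threshold,
        )
        for level in levels:
            schedule = make_schedule({"fixed": level}, n_tasks=n_tasks)
            for rep in range(replicates):
                seed = replicate_seed(base_seed, float(lam), level, rep)
                record = run_evolution(
                    cell_params, schedule, success_table, seed=seed, fast=fast
                )
                stats = summarize_evolution(record, window=window)
                row = {
                    "update_rate": float(lam),
                    "obstacle": level,
                    "replicate": rep,
                    "seed": seed,
                }
                row.update(stats.to_flat_dict(include_shares=False))
                rows.append(row)
    runs = pd.DataFrame(rows)
    value_cols = [
        c
        for c in runs.columns
        if c not in ("update_rate", "obstacle", "replicate", "seed")
    ]
    grouped = runs.groupby(["update_rate", "obstacle"], sort=False)[value_cols]
    aggregates = grouped.agg(["mean", "sem"])
    aggregates.columns = [f"{col}_{stat}" for col, stat in aggregates.columns]
    aggregates = aggregates.reset_index()
    return runs, aggregates
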