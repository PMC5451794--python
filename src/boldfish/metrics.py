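"""Windowed summary statistics over evolution records.

All headline quantities are computed over a statistics window — by
default the last 100 of 200 tasks, where the evolutionary process has
stabilised:

* ``mean_trait`` — average boldness s̄ across agents and window tasks;
* ``mean_n_bold`` / ``mean_n_coop`` — average counts of bold agents
  (s_i > 0.7) and cooperators per task;
* ``initiator_shares`` — p_i, each agent's fraction of window tasks it
  initiated;
* ``diversity`` — d_I, the population standard deviation of the p_i: 0
  when every agent initiates equally often, √(N−1)/N when one agent
  always initiates;
* ``mean_decision_time`` — average winning decision time of the race;
* ``mean_cost`` / ``mean_payoff`` — per-capita per-task cost c·n_C/N and
  pay-off Σπ/N, which satisfy cost + payoff = r·b on every task;
* ``success_rate`` — fraction of window tasks with r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidStateError, UnsupportedVariantError
from .evolution import EvolutionRecord, VARIANT_PERSONALITY
from .game import GameParams, PersonalityState, TaskRecord

__all__ = [
    "DEFAULT_WINDOW",
    "SummaryStats",
    "resolve_window",
    "initiator_shares",
    "diversity_index",
    "count_roles",
    "summarize_evolution",
]

DEFAULT_WINDOW = 100


@dataclass(frozen=True)
class SummaryStats:
    """Windowed averages of one evolution; see the module docstring."""

    window: tuple[int, int]
    mean_trait: float
    mean_n_bold: float
    mean_n_coop: float
    diversity: float | None
    mean_decision_time: float | None
    mean_cost: float
    mean_payoff: float
    success_rate: float
    initiator_shares: tuple[float, ...] | None

    def to_flat_dict(self, include_shares: bool = True) -> dict:
        flat = {
            "window_start": self.window[0],
            "window_stop": self.window[1],
            "mean_trait": self.mean_trait,
            "mean_n_bold": self.mean_n_bold,
            "mean_n_coop": self.mean_n_coop,
            "diversity": self.diversity,
            "mean_decision_time": self.mean_decision_time,
            "mean_cost": self.mean_cost,
            "mean_payoff": self.mean_payoff,
            "success_rate": self.success_rate,
        }
        if include_shares and self.initiator_shares is not None:
            for i, p in enumerate(self.initiator_shares):
                flat[f"initiator_share_{i + 1}"] = p
        return flat


def resolve_window(
    record_length: int, window: int | tuple[int, int] | None
) -> tuple[int, int]:
    """Normalise a window spec to a 0-based half-open ``(start, stop)``.

    ``None`` means the trailing :data:`DEFAULT_WINDOW` tasks (or the whole
    record if shorter); an integer ``w`` means the trailing ``w`` tasks.
    """
    if window is None:
        window = min(DEFAULT_WINDOW, record_length)
    if isinstance(window, int):
        if window < 1:
            raise InvalidStateError(f"window must be at least 1 task, got {window!r}")
        if window > record_length:
            raise InvalidStateError(
                f"window of {window} tasks exceeds record length {record_length}"
            )
        return (record_length - window, record_length)
    start, stop = window
    if not (0 <= start < stop <= record_length):
        raise InvalidStateError(
            f"window ({start}, {stop}) is empty or outside the record "
            f"of length {record_length}"
        )
    return (int(start), int(stop))


def initiator_shares(
    record: EvolutionRecord, window: int | tuple[int, int] | None = None
) -> np.ndarray:
    """Fraction of window tasks each agent initiated; sums to one."""
    if record.model_variant != VARIANT_PERSONALITY:
        raise UnsupportedVariantError(
            f"initiator shares are undefined for variant {record.model_variant!r}: "
            "the reference model has no initiator"
        )
    start, stop = resolve_window(len(record), window)
    counts = np.zeros(record.params.n_agents)
    for task in record.tasks[start:stop]:
        counts[task.initiator] += 1
    return counts / (stop - start)


def diversity_index(shares: Sequence[float] | np.ndarray) -> float:
    """Degree of initiator-role diversity d_I.

    The population standard deviation (divide-by-N, not N−1) of the
    initiator shares::

        d_I = sqrt( (1/N) Σ_i (p_i − p̄)² )

    Zero when the role rotates uniformly; the maximum √(N−1)/N is
    attained exactly when a single agent always initiates.
    """
    shares = np.asarray(shares, dtype=float)
    if shares.ndim != 1 or shares.size == 0:
        raise InvalidStateError("shares must be a nonempty 1-d vector")
    return float(np.std(shares))


def count_roles(
    task_or_traits: TaskRecord | PersonalityState | np.ndarray,
    params: GameParams,
) -> tuple[int | None, int, int]:
    """Count ``(n_C, n_B, n_shy)`` for a task record or a bare trait vector.

    ``n_B`` and ``n_shy`` use strict inequalities against the bold/shy
    thresholds.  For a bare trait vector there is no role assignment, so
    ``n_C`` is ``None``.
    """
    if isinstance(task_or_traits, TaskRecord):
        traits = task_or_traits.traits_after.traits
        n_coop: int | None = task_or_traits.n_cooperators
    elif isinstance(task_or_traits, PersonalityState):
        traits = task_or_traits.traits
        n_coop = None
    else:
        traits = np.asarray(task_or_traits, dtype=float)
        n_coop = None
    n_bold = int(np.sum(traits > params.bold_threshold))
    n_shy = int(np.sum(traits < params.shy_threshold))
    return n_coop, n_bold, n_shy


def summarize_evolution(
    record: EvolutionRecord, window: int | tuple[int, int] | None = None
) -> SummaryStats:
    """Windowed summary of a whole evolution (default: last 100 tasks)."""
    start, stop = resolve_window(len(record), window)
    tasks = record.tasks[start:stop]
    params = record.params
    n = params.n_agents

    mean_trait = float(np.mean([t.traits_after.traits.mean() for t in tasks]))
    mean_n_bold = float(np.mean([t.n_bold for t in tasks]))
    mean_n_coop = float(np.mean([t.n_cooperators for t in tasks]))
    mean_cost = float(np.mean([params.cost * t.n_cooperators / n for t in tasks]))
    mean_payoff = float(np.mean([t.payoffs.sum() / n for t in tasks]))
    success_rate = float(np.mean([t.outcome for t in tasks]))

    if record.has_race:
        shares = initiator_shares(record, (start, stop))
        diversity = diversity_index(shares)
        mean_decision_time = float(np.mean([t.decision_time for t in tasks]))
        shares_out: tuple[float, ...] | None = tuple(shares)
    else:
        shares_out = None
        diversity = None
        mean_decision_time = None

    return SummaryStats(
        window=(start, stop),
        mean_trait=mean_trait,
        mean_n_bold=mean_n_bold,
        mean_n_coop=mean_n_coop,
        diversity=diversity,
        mean_decision_time=mean_decision_time,
        mean_cost=mean_cost,
        mean_payoff=mean_payoff,
        success_rate=success_rate,
        initiator_shares=shares_out,
    )
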