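"""Task-success environment: obstacle difficulty → success probability.

The physical task — a group of robotic fish pushing a weighted obstacle
out of their path within a time limit — is abstracted into a table of
success probabilities keyed by (obstacle level, number of cooperators).
Four difficulty levels O1 < O2 < O3 < O4 correspond to obstacle weights
of 1.6, 2.0, 2.5 and 2.9 kg.  Empirically pinned cells:

* a single cooperator removes O1 in 17% of attempts and never removes
  O2–O4;
* two cooperators always remove O1 and never O2–O4;
* six cooperators always succeed, at every level.

Cells not pinned by those statements use a deterministic threshold fill
(success iff n_C reaches 2/3/4/5 cooperators for O1..O4), which is
monotone in both the number of cooperators and the difficulty order.
A run configuration may override the whole table with an explicit
level × n_C matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "OBSTACLE_LEVELS",
    "OBSTACLE_WEIGHTS_KG",
    "DEFAULT_COOPERATOR_THRESHOLDS",
    "SuccessTable",
    "build_default_success_table",
    "success_probability",
    "sample_outcome",
    "validate_success_table",
]

OBSTACLE_LEVELS: tuple[str, ...] = ("O1", "O2", "O3", "O4")

#: Physical obstacle weights, kilograms; difficulty increases with weight.
OBSTACLE_WEIGHTS_KG: dict[str, float] = {"O1": 1.6, "O2": 2.0, "O3": 2.5, "O4": 2.9}

#: Minimum cooperators for guaranteed success in the default threshold fill.
DEFAULT_COOPERATOR_THRESHOLDS: dict[str, int] = {"O1": 2, "O2": 3, "O3": 4, "O4": 5}


@dataclass(frozen=True)
class SuccessTable:
    """Mapping ``(obstacle level, n_C)`` → success probability in [0, 1]."""

    probabilities: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        frozen = dict(self.probabilities)
        for key, p in frozen.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"success probability out of [0, 1] at cell {key}: {p!r}"
                )
        object.__setattr__(self, "probabilities", frozen)

    @property
    def levels(self) -> tuple[str, ...]:
        seen = dict.fromkeys(level for level, _ in self.probabilities)
        return tuple(seen)

    def max_cooperators(self, level: str) -> int:
        return max(n for lv, n in self.probabilities if lv == level)

    @classmethod
    def from_matrix(cls, matrix: Mapping[str, "list[float]"]) -> "SuccessTable":
        """Build from ``{level: [p(n_C=1), p(n_C=2), ...]}`` as read from config."""
        probabilities = {
            (level, n + 1): float(p)
            for level, row in matrix.items()
            for n, p in enumerate(row)
        }
        return cls(probabilities)

    def to_matrix(self) -> dict[str, list[float]]:
        return {
            level: [
                self.probabilities[(level, n)]
                for n in range(1, self.max_cooperators(level) + 1)
            ]
            for level in self.levels
        }


def build_default_success_table(n_agents: int = 6) -> SuccessTable:
    """Default table: threshold fill plus the pinned 17% single-pusher cell."""
    if n_agents < 1:
        raise ConfigurationError(f"n_agents must be at least 1, got {n_agents!r}")
    probabilities: dict[tuple[str, int], float] = {}
    for level in OBSTACLE_LEVELS:
        threshold = DEFAULT_COOPERATOR_THRESHOLDS[level]
        for n_coop in range(1, n_agents + 1):
            probabilities[(level, n_coop)] = 1.0 if n_coop >= threshold else 0.0
    if n_agents >= 1:
        probabilities[("O1", 1)] = 0.17
    return SuccessTable(probabilities)


def success_probability(table: SuccessTable, obstacle: str, n_coop: int) -> float:
    """Look up the stored probability; missing cells are a configuration error."""
    try:
        return table.probabilities[(obstacle, n_coop)]
    except KeyError:
        raise ConfigurationError(
            f"success table has no cell for obstacle {obstacle!r} with "
            f"n_C={n_coop}; available levels: {table.levels}"
        ) from None


def sample_outcome(
    table: SuccessTable, obstacle: str, n_coop: int, rng: np.random.Generator
) -> int:
    """Bernoulli task outcome ``r``; deterministic when the cell is 0 or 1."""
    p = success_probability(table, obstacle, n_coop)
    if p >= 1.0:
        return 1
    if p <= 0.0:
        return 0
    return int(rng.random() < p)


def validate_success_table(table: SuccessTable) -> list[str]:
    """Report every monotonicity violation; an empty list means the table is sound.

    Success must not decrease with more cooperators at a fixed level, and
    must not increase with difficulty at a fixed number of cooperators.
    """
    violations: list[str] = []
    probs = table.probabilities
    levels = [lv for lv in OBSTACLE_LEVELS if lv in table.levels]
    levels += [lv for lv in table.levels if lv not in OBSTACLE_LEVELS]
    for level in levels:
        ns = sorted(n for lv, n in probs if lv == level)
        for lo, hi in zip(ns, ns[1:]):
            if probs[(level, hi)] < probs[(level, lo)]:
                violations.append(
                    f"success at ({level}, n_C={hi}) = {probs[(level, hi)]} is below "
                    f"({level}, n_C={lo}) = {probs[(level, lo)]}"
                )
    for easier, harder in zip(levels, levels[1:]):
        shared = sorted(
            {n for lv, n in probs if lv == easier} & {n for lv, n in probs if lv == harder}
        )
        for n in shared:
            if probs[(harder, n)] > probs[(easier, n)]:
                violations.append(
                    f"success at ({harder}, n_C={n}) = {probs[(harder, n)]} exceeds "
                    f"({easier}, n_C={n}) = {probs[(easier, n)]}"
                )
    return violations
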