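"""Single-stage-game mechanics of the boldness-driven foraging game.

A group of ``N`` agents repeatedly faces a collective task (removing an
obstacle).  Each agent ``i`` carries a personality trait, *boldness*
``s_i ∈ (0, 1)``, which is simultaneously its strategy in an N-player
snowdrift game played in extensive form:

1. **Initiator race** — each agent draws an exponential "decision time"
   with rate ``s_i`` (mean ``1/s_i``); the agent with the smallest draw
   becomes the *initiator*.  The winner of this race is distributed as
   ``P(i) = s_i / Σ_m s_m``, so bolder agents initiate more often.
2. **Role assignment** — every other agent independently joins as a
   *follower* with probability ``1 − s_i²`` and free-rides otherwise.
   Initiator and followers together are the cooperators (C-players).
3. **Outcome and payoffs** — the task succeeds (``r = 1``) with a
   probability that depends on the obstacle and on the number of
   cooperators ``n_C``.  C-players earn ``r·b − c``; free-riders (D)
   earn ``r·b``, with benefit ``b`` strictly above cost ``c``.
4. **Reinforcement** — only the initiator learns:
   ``s ← r·λ + s·(1 − λ)`` with update rate ``λ ∈ (0, 1)``, so success
   pulls its boldness toward 1 and failure toward 0.

All randomness flows through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, InvalidStateError

__all__ = [
    "ROLE_INITIATOR",
    "ROLE_FOLLOWER",
    "ROLE_FREE_RIDER",
    "ROLE_COOPERATOR",
    "GameParams",
    "PersonalityState",
    "RoleAssignment",
    "TaskRecord",
    "sample_decision_times",
    "select_initiator",
    "initiator_distribution",
    "assign_roles",
    "compute_payoffs",
    "update_initiator_trait",
    "play_stage_game",
]

ROLE_INITIATOR = "initiator"
ROLE_FOLLOWER = "follower"
ROLE_FREE_RIDER = "free_rider"
#: Cooperator label used by the reference model, which has no initiator race.
ROLE_COOPERATOR = "cooperator"

#: Roles whose bearer pays the cooperation cost.
_C_ROLES = frozenset({ROLE_INITIATOR, ROLE_FOLLOWER, ROLE_COOPERATOR})

# Representable closure of the open unit interval: trait updates are clamped
# here so that float rounding can never push a trait onto 0.0 or 1.0 exactly.
_TRAIT_LO = np.nextafter(0.0, 1.0)
_TRAIT_HI = np.nextafter(1.0, 0.0)


@dataclass(frozen=True)
class GameParams:
    """Parameters of the stage game.

    Parameters
    ----------
    n_agents
        Group size ``N``.
    benefit, cost
        Snowdrift payoff parameters ``b > c > 0``; every agent receives
        ``b`` on success, cooperators pay ``c`` regardless of outcome.
    update_rate
        Reinforcement rate ``λ ∈ (0, 1)`` of the initiator's trait update.
    bold_threshold, shy_threshold
        An agent is counted "bold" when ``s_i > bold_threshold`` and
        "shy" when ``s_i < shy_threshold`` (strict inequalities).
    """

    n_agents: int = 6
    benefit: float = 2.0
    cost: float = 1.0
    update_rate: float = 0.9
    bold_threshold: float = 0.7
    shy_threshold: float = 0.3

    def __post_init__(self) -> None:
        problems = []
        if not (isinstance(self.n_agents, (int, np.integer)) and self.n_agents >= 1):
            problems.append(f"n_agents must be a positive integer, got {self.n_agents!r}")
        if not self.cost > 0:
            problems.append(f"cost must be positive, got {self.cost!r}")
        if not self.benefit > self.cost:
            problems.append(
                f"benefit must exceed cost, got benefit={self.benefit!r} cost={self.cost!r}"
            )
        if not 0.0 < self.update_rate < 1.0:
            problems.append(f"update_rate must lie in (0, 1), got {self.update_rate!r}")
        if not 0.0 < self.shy_threshold < self.bold_threshold < 1.0:
            problems.append(
                "thresholds must satisfy 0 < shy_threshold < bold_threshold < 1, got "
                f"shy={self.shy_threshold!r} bold={self.bold_threshold!r}"
            )
        if problems:
            raise DomainError("; ".join(problems))


@dataclass(frozen=True)
class PersonalityState:
    """Boldness traits ``s_1..s_N``, each strictly inside the unit interval."""

    traits: np.ndarray

    def __post_init__(self) -> None:
        traits = np.asarray(self.traits, dtype=float)
        object.__setattr__(self, "traits", traits)
        if traits.ndim != 1 or traits.size == 0:
            raise InvalidStateError("traits must be a nonempty 1-d vector")
        if not (np.all(traits > 0.0) and np.all(traits < 1.0)):
            raise DomainError(
                f"all traits must lie strictly in (0, 1), got {traits!r}"
            )

    @property
    def n_agents(self) -> int:
        return self.traits.size

    def replace_trait(self, index: int, value: float) -> "PersonalityState":
        traits = self.traits.copy()
        traits[index] = value
        return PersonalityState(traits)


@dataclass(frozen=True)
class RoleAssignment:
    """Outcome of one initiator race plus follower/free-rider draws.

    ``decision_times`` is ``None`` for the reference model, which has no
    race; in that case ``initiator`` is ``None`` as well.
    """

    decision_times: np.ndarray | None
    initiator: int | None
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.initiator is not None:
            if not 0 <= self.initiator < len(self.roles):
                raise InvalidStateError(f"initiator index {self.initiator} out of range")
            if self.roles.count(ROLE_INITIATOR) != 1 or self.roles[self.initiator] != ROLE_INITIATOR:
                raise InvalidStateError("exactly the initiator must carry the initiator role")
            if self.decision_times is not None and (
                int(np.argmin(self.decision_times)) != self.initiator
            ):
                raise InvalidStateError("initiator must be the argmin of decision_times")

    @property
    def n_cooperators(self) -> int:
        return sum(role in _C_ROLES for role in self.roles)


@dataclass(frozen=True)
class TaskRecord:
    """Complete outcome of one stage game.

    ``traits_after`` is the trait vector *after* the initiator's update,
    i.e. the state carried into the next task.
    """

    task_index: int
    obstacle: str
    role_assignment: RoleAssignment
    n_cooperators: int
    n_bold: int
    outcome: int
    payoffs: np.ndarray
    traits_after: PersonalityState

    @property
    def initiator(self) -> int | None:
        return self.role_assignment.initiator

    @property
    def roles(self) -> tuple[str, ...]:
        return self.role_assignment.roles

    @property
    def decision_time(self) -> float | None:
        """The winning (smallest) decision time, or ``None`` without a race."""
        times = self.role_assignment.decision_times
        if times is None:
            return None
        return float(times[self.role_assignment.initiator])


def sample_decision_times(
    state: PersonalityState, rng: np.random.Generator
) -> np.ndarray:
    """Draw one exponential decision time per agent, rate ``s_i``.

    Draw ``i`` has density ``s_i·exp(−s_i·t)`` on ``t ≥ 0`` and mean
    ``1/s_i``, so bold agents tend to decide sooner.
    """
    traits = state.traits
    return rng.exponential(scale=1.0 / traits)


def select_initiator(decision_times: Sequence[float] | np.ndarray) -> int:
    """Index of the smallest decision time; ties break to the lowest index.

    Ties have probability zero under continuous sampling; the rule exists
    so that degenerate, hand-constructed inputs stay reproducible.
    """
    times = np.asarray(decision_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise InvalidStateError("decision_times must be a nonempty 1-d vector")
    if np.any(times < 0):
        raise DomainError("decision times must be nonnegative")
    return int(np.argmin(times))


def initiator_distribution(state: PersonalityState) -> np.ndarray:
    """Exact win probabilities of the race: ``p_m = s_m / Σ_i s_i``."""
    traits = state.traits
    return traits / traits.sum()


def assign_roles(
    state: PersonalityState, initiator: int, rng: np.random.Generator
) -> tuple[str, ...]:
    """Label every agent: the initiator plus independent follower draws.

    Each non-initiator becomes a follower with probability ``1 − s_i²``
    (bolder agents are less responsive to someone else's initiative) and
    a free-rider with probability ``s_i²``.
    """
    n = state.n_agents
    if not 0 <= initiator < n:
        raise InvalidStateError(f"initiator index {initiator} out of range for N={n}")
    u = rng.random(n)
    roles = [
        ROLE_FREE_RIDER if u[i] < state.traits[i] ** 2 else ROLE_FOLLOWER
        for i in range(n)
    ]
    roles[initiator] = ROLE_INITIATOR
    return tuple(roles)


def compute_payoffs(
    roles: Sequence[str], outcome: int, params: GameParams
) -> np.ndarray:
    """Snowdrift payoffs: C-players get ``r·b − c``, D-players ``r·b``."""
    if outcome not in (0, 1):
        raise DomainError(f"outcome must be 0 or 1, got {outcome!r}")
    rb = outcome * params.benefit
    return np.array(
        [rb - params.cost if role in _C_ROLES else rb for role in roles]
    )


def update_initiator_trait(
    state: PersonalityState, initiator: int, outcome: int, params: GameParams
) -> PersonalityState:
    """Reinforce only the initiator: ``s ← r·λ + s·(1 − λ)``.

    The exact update maps (0, 1) into (r·λ, r·λ + 1 − λ) ⊂ (0, 1); the
    result is clamped to the nearest representable interior floats so
    that rounding can never produce exactly 0.0 or 1.0.
    """
    if outcome not in (0, 1):
        raise DomainError(f"outcome must be 0 or 1, got {outcome!r}")
    if not 0 <= initiator < state.n_agents:
        raise InvalidStateError(f"initiator index {initiator} out of range")
    lam = params.update_rate
    new_value = outcome * lam + state.traits[initiator] * (1.0 - lam)
    new_value = min(max(new_value, _TRAIT_LO), _TRAIT_HI)
    return state.replace_trait(initiator, new_value)


def play_stage_game(
    state: PersonalityState,
    obstacle: str,
    success_table,
    params: GameParams,
    rng: np.random.Generator,
    task_index: int = 0,
    fast: bool = False,
) -> TaskRecord:
    """Play one full task: race → roles → outcome → payoffs → update.

    Parameters
    ----------
    fast
        When true, skip the explicit per-agent race: sample the initiator
        directly from ``s_m / Σ s_i`` and its decision time from the
        exponential-minimum law ``Exp(Σ s_i)``.  Distributionally
        equivalent to the explicit race, but the losers' decision times
        are not materialised (they are recorded as ``+inf``).
    """
    from .environment import sample_outcome  # local import avoids a cycle

    if fast:
        probs = initiator_distribution(state)
        initiator = int(rng.choice(state.n_agents, p=probs))
        winning_time = rng.exponential(scale=1.0 / state.traits.sum())
        decision_times = np.full(state.n_agents, np.inf)
        decision_times[initiator] = winning_time
    else:
        decision_times = sample_decision_times(state, rng)
        initiator = select_initiator(decision_times)

    roles = assign_roles(state, initiator, rng)
    assignment = RoleAssignment(decision_times, initiator, roles)
    n_coop = assignment.n_cooperators
    outcome = sample_outcome(success_table, obstacle, n_coop, rng)
    payoffs = compute_payoffs(roles, outcome, params)
    new_state = update_initiator_trait(state, initiator, outcome, params)
    n_bold = int(np.sum(new_state.traits > params.bold_threshold))
    return TaskRecord(
        task_index=task_index,
        obstacle=obstacle,
        role_assignment=assignment,
        n_cooperators=n_coop,
        n_bold=n_bold,
        outcome=outcome,
        payoffs=payoffs,
        traits_after=new_state,
    )
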