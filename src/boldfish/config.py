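"""Run configuration: defaults, validation, YAML/JSON loading.

An empty configuration reproduces the canonical experimental settings:
a group of 6 agents, benefit 2, cost 1, 200 tasks per evolution, summary
statistics over the last 100 tasks, the default success table, and the
personality model.  The physical 60-second task limit of the original
set-up is not simulated; timeouts are already folded into the success
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .environment import (
    OBSTACLE_LEVELS,
    SuccessTable,
    build_default_success_table,
    validate_success_table,
)
from .errors import ConfigurationError
from .evolution import (
    DEFAULT_N_TASKS,
    VARIANT_PERSONALITY,
    VARIANT_REFERENCE_EVOLVING,
    VARIANT_REFERENCE_FIXED,
    Schedule,
    make_schedule,
)
from .game import GameParams

__all__ = ["RunConfig", "load_config"]

_VARIANTS = (VARIANT_PERSONALITY, VARIANT_REFERENCE_FIXED, VARIANT_REFERENCE_EVOLVING)


@dataclass(frozen=True)
class RunConfig:
    """Fully validated description of one run (or sweep cell)."""

    n_agents: int = 6
    benefit: float = 2.0
    cost: float = 1.0
    update_rate: float = 0.9
    bold_threshold: float = 0.7
    shy_threshold: float = 0.3
    n_tasks: int = DEFAULT_N_TASKS
    stats_window: int = 100
    schedule: Mapping[str, object] = field(default_factory=lambda: {"fixed": "O1"})
    success_table: str | Mapping[str, list] = "default"
    model_variant: str = VARIANT_PERSONALITY
    seed: int | None = None
    replicates: int = 5
    output_dir: str = "."

    def game_params(self) -> GameParams:
        return GameParams(
            n_agents=self.n_agents,
            benefit=self.benefit,
            cost=self.cost,
            update_rate=self.update_rate,
            bold_threshold=self.bold_threshold,
            shy_threshold=self.shy_threshold,
        )

    def build_schedule(self) -> Schedule:
        return make_schedule(dict(self.schedule), n_tasks=self.n_tasks)

    def build_success_table(self) -> SuccessTable:
        if self.success_table == "default":
            return build_default_success_table(self.n_agents)
        return SuccessTable.from_matrix(self.success_table)

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "benefit": self.benefit,
            "cost": self.cost,
            "update_rate": self.update_rate,
            "bold_threshold": self.bold_threshold,
            "shy_threshold": self.shy_threshold,
            "n_tasks": self.n_tasks,
            "stats_window": self.stats_window,
            "schedule": dict(self.schedule),
            "success_table": (
                "default"
                if self.success_table == "default"
                else dict(self.success_table)
            ),
            "model_variant": self.model_variant,
            "seed": self.seed,
            "replicates": self.replicates,
            "output_dir": self.output_dir,
        }


def _collect_errors(cfg: RunConfig) -> list[str]:
    problems: list[str] = []
    if not (isinstance(cfg.n_agents, int) and cfg.n_agents >= 1):
        problems.append(f"n_agents: must be a positive integer, got {cfg.n_agents!r}")
    if not cfg.cost > 0:
        problems.append(f"cost: must be positive, got {cfg.cost!r}")
    if not cfg.benefit > cfg.cost:
        problems.append(
            f"benefit: benefit must exceed cost (got b={cfg.benefit!r}, c={cfg.cost!r})"
        )
    if not 0.0 < cfg.update_rate < 1.0:
        problems.append(
            f"update_rate: must lie strictly in (0, 1), got {cfg.update_rate!r}"
        )
    if not 0.0 < cfg.shy_threshold < cfg.bold_threshold < 1.0:
        problems.append(
            "thresholds: need 0 < shy_threshold < bold_threshold < 1, got "
            f"shy={cfg.shy_threshold!r}, bold={cfg.bold_threshold!r}"
        )
    if not (isinstance(cfg.n_tasks, int) and cfg.n_tasks >= 1):
        problems.append(f"n_tasks: must be a positive integer, got {cfg.n_tasks!r}")
    if not (isinstance(cfg.stats_window, int) and 1 <= cfg.stats_window <= cfg.n_tasks):
        problems.append(
            f"stats_window: must be an integer in 1..n_tasks, got {cfg.stats_window!r}"
        )
    if cfg.model_variant not in _VARIANTS:
        problems.append(
            f"model_variant: must be one of {_VARIANTS}, got {cfg.model_variant!r}"
        )
    if not (isinstance(cfg.replicates, int) and cfg.replicates >= 1):
        problems.append(f"replicates: must be a positive integer, got {cfg.replicates!r}")
    if cfg.seed is not None and not isinstance(cfg.seed, int):
        problems.append(f"seed: must be an integer or null, got {cfg.seed!r}")

    try:
        cfg.build_schedule()
    except ConfigurationError as exc:
        problems.append(f"schedule: {exc}")

    if cfg.success_table != "default":
        if not isinstance(cfg.success_table, Mapping):
            problems.append(
                "success_table: must be 'default' or a {level: [probabilities]} mapping"
            )
        else:
            try:
                table = SuccessTable.from_matrix(cfg.success_table)
            except (ConfigurationError, TypeError, ValueError) as exc:
                problems.append(f"success_table: {exc}")
            else:
                for violation in validate_success_table(table):
                    problems.append(f"success_table: {violation}")
                bad_levels = [lv for lv in table.levels if lv not in OBSTACLE_LEVELS]
                if bad_levels:
                    problems.append(
                        f"success_table: unknown obstacle level(s) {bad_levels}"
                    )
    return problems


def load_config(source: str | Path | Mapping | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``source`` may be a YAML/JSON file path, an in-memory mapping, or
    ``None``/empty for all defaults.  Validation reports *every*
    offending key at once.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"configuration file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed configuration in {path}: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigurationError(
                f"configuration root must be a mapping, got {type(raw).__name__}"
            )
        raw = dict(raw)

    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(
            "unknown configuration key(s): " + ", ".join(unknown)
        )
    cfg = RunConfig(**raw)
    problems = _collect_errors(cfg)
    if problems:
        raise ConfigurationError("invalid configuration:\n  " + "\n  ".join(problems))
    return cfg
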