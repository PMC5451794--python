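"""Record and summary serialization: per-task CSV plus a JSON run summary.

Floats are written with Python's shortest round-trip ``repr``, so every
value survives a write/read cycle bit-for-bit and identical runs produce
byte-identical files.  The per-task CSV has one row per task with
columns::

    task_index, obstacle, initiator, role_1..role_N, n_C, n_B, r,
    decision_time, payoff_1..payoff_N, trait_1..trait_N

``initiator`` and ``decision_time`` are empty for reference-model runs,
which have no initiator race.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidStateError
from .evolution import EvolutionRecord
from .metrics import summarize_evolution

__all__ = ["task_columns", "record_to_frame", "export_records", "load_run"]

TASKS_CSV = "tasks.csv"
SUMMARY_JSON = "summary.json"


def task_columns(n_agents: int) -> list[str]:
    return (
        ["task_index", "obstacle", "initiator"]
        + [f"role_{i + 1}" for i in range(n_agents)]
        + ["n_C", "n_B", "r", "decision_time"]
        + [f"payoff_{i + 1}" for i in range(n_agents)]
        + [f"trait_{i + 1}" for i in range(n_agents)]
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _task_row(task) -> list:
    return (
        [task.task_index, task.obstacle, task.initiator]
        + list(task.roles)
        + [task.n_cooperators, task.n_bold, task.outcome, task.decision_time]
        + [float(p) for p in task.payoffs]
        + [float(s) for s in task.traits_after.traits]
    )


def record_to_frame(record: EvolutionRecord) -> pd.DataFrame:
    """Tabular view of a record, one row per task."""
    cols = task_columns(record.params.n_agents)
    return pd.DataFrame([_task_row(t) for t in record.tasks], columns=cols)


def export_records(
    record: EvolutionRecord,
    out_dir: str | Path,
    config: dict | None = None,
    window: int | tuple[int, int] | None = None,
) -> tuple[Path, Path]:
    """Write ``tasks.csv`` and ``summary.json`` under ``out_dir``.

    Returns the two paths.  ``config``, when given, is embedded verbatim
    in the summary so a run can be reproduced from its outputs alone.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InvalidStateError(f"cannot create output directory {out}: {exc}") from exc

    csv_path = out / TASKS_CSV
    cols = task_columns(record.params.n_agents)
    try:
        with csv_path.open("w", newline="") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(cols)
            for task in record.tasks:
                writer.writerow([_fmt(v) for v in _task_row(task)])
    except OSError as exc:
        raise InvalidStateError(f"cannot write {csv_path}: {exc}") from exc

    stats = summarize_evolution(record, window=window)
    summary = {
        "seed": record.seed,
        "model_variant": record.model_variant,
        "n_agents": record.params.n_agents,
        "benefit": record.params.benefit,
        "cost": record.params.cost,
        "update_rate": record.params.update_rate,
        "bold_threshold": record.params.bold_threshold,
        "shy_threshold": record.params.shy_threshold,
        "n_tasks": len(record),
        "initial_traits": [float(s) for s in record.initial_traits],
        "summary_stats": stats.to_flat_dict(),
    }
    if config is not None:
        summary["config"] = config
    json_path = out / SUMMARY_JSON
    try:
        json_path.write_text(json.dumps(summary, indent=2) + "\n")
    except OSError as exc:
        raise InvalidStateError(f"cannot write {json_path}: {exc}") from exc
    return csv_path, json_path


def load_run(out_dir: str | Path) -> tuple[dict, pd.DataFrame]:
    """Read back a run: ``(summary dict, per-task DataFrame)``.

    Numeric columns come back as exact float64 values; ``initiator`` and
    ``decision_time`` are NaN-free nullable columns for personality runs
    and all-null for reference runs.
    """
    out = Path(out_dir)
    summary = json.loads((out / SUMMARY_JSON).read_text())
    n = summary["n_agents"]
    frame = pd.read_csv(
        out / TASKS_CSV,
        dtype={
            "task_index": int,
            "obstacle": str,
            "n_C": int,
            "n_B": int,
            "r": int,
            **{f"role_{i + 1}": str for i in range(n)},
        },
        float_precision="round_trip",
    )
    return summary, frame
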