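"""Readers and writers for session logs, configurations and results.

Session logs are plain CSV, one row per trial::

    trial,target_color,target_shape,target_number,action,feedback,true_rule

``true_rule`` may be empty for observed human data (it is reconstructed
from the protocol when fitting).  Configurations are YAML or JSON mappings
of :class:`~cardsort.task.TaskConfig` fields; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agent import Session, TrialRecord
from .task import Card, TaskConfig, match_vector

__all__ = [
    "read_session",
    "write_session",
    "write_beliefs",
    "write_trajectory",
    "write_posterior",
    "load_task_config",
]

REQUIRED_COLUMNS = (
    "trial",
    "target_color",
    "target_shape",
    "target_number",
    "action",
    "feedback",
)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session log as CSV (lossless for the observable fields)."""
    session.to_frame().to_csv(path, index=False)


def read_session(path: str | Path, config: TaskConfig | None = None) -> Session:
    """Read and validate a session CSV.

    Raises ``ValueError`` naming the offending rows for missing columns,
    out-of-range feature/action codes, feedback outside {0, 1}, or
    non-consecutive trial indices.  An empty file is an error, not an empty
    session.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty session file") from None
    if df.empty:
        raise ValueError(f"{path}: session file contains no trials")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    def _bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = [int(r) + 2 for r in df.index[mask][:5]]  # 1-based + header
            raise ValueError(f"{path}: {what} in file rows {rows}")

    for col in ("target_color", "target_shape", "target_number", "action"):
        _bad_rows(~df[col].isin([1, 2, 3, 4]), f"{col} outside 1..4")
    _bad_rows(~df["feedback"].isin([0, 1]), "feedback outside {0, 1}")
    if not (df["trial"].to_numpy() == np.arange(1, len(df) + 1)).all():
        raise ValueError(f"{path}: trial indices must run 1..{len(df)} consecutively")

    has_rule = "true_rule" in df.columns and df["true_rule"].notna().all()
    if has_rule:
        _bad_rows(~df["true_rule"].isin([1, 2, 3]), "true_rule outside 1..3")

    trials = []
    for _, row in df.iterrows():
        target = Card(
            int(row.target_color), int(row.target_shape), int(row.target_number)
        )
        action = int(row.action)
        trials.append(
            TrialRecord(
                t=int(row.trial),
                target=target,
                action=action,
                feedback=int(row.feedback),
                match=match_vector(target, action),
                true_rule=int(row.true_rule) if has_rule else None,
            )
        )
    return Session(trials=trials, config=config or TaskConfig())


def write_beliefs(session: Session, path: str | Path) -> None:
    """Per-trial belief dump: prior_1..3, post_1..3, omega_1..3 columns."""
    session.to_frame(beliefs=True).to_csv(path, index=False)


def write_trajectory(trajectory, path: str | Path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def write_posterior(posterior, prefix: str | Path) -> tuple[Path, Path]:
    """Write a grid posterior as <prefix>.csv (node masses) and
    <prefix>.json (means, medians, 95% intervals)."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    posterior.to_frame().to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(posterior.summary(), indent=2))
    return csv_path, json_path


def load_task_config(path: str | Path) -> TaskConfig:
    """Load a TaskConfig from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(TaskConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "rule_sequence" in data:
        data["rule_sequence"] = tuple(data["rule_sequence"])
    if "fixed_targets" in data and data["fixed_targets"] is not None:
        data["fixed_targets"] = tuple(Card(*c) for c in data["fixed_targets"])
    return TaskConfig(**data)
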