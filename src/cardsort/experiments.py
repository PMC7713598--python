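"""Scripted simulation designs: factorial clinical-scoring cohorts,
information-dynamics sweeps, and synthetic multi-group cohorts.

These are the package's fixture factories: every study regenerates its data
from a master seed, with per-agent substreams spawned deterministically so
cohorts are reproducible and embarrassingly parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .agent import AgentParams, Session, run_agent
from .info import InfoTrajectory, reconstruct_trajectories
from .scoring import score_session
from .task import TaskConfig

__all__ = [
    "FactorialDesign",
    "CohortTable",
    "run_factorial",
    "simulate_cohort",
    "run_info_dynamics",
    "synthetic_cohort",
]

#: The factorial grid used for the clinical-scoring study: flexibility at
#: four levels crossed with information loss at three, 150 agents per cell.
CLINICAL_LAM_LEVELS = (0.3, 0.5, 0.7, 0.9)
CLINICAL_DELTA_LEVELS = (0.4, 0.7, 0.9)

#: The 3x3 grid used for the information-dynamics study.
DYNAMICS_LEVELS = (0.1, 0.5, 0.9)

MEASURES = ("E", "PE", "TFC", "FMS")


@dataclass(frozen=True)
class FactorialDesign:
    lam_levels: tuple[float, ...] = CLINICAL_LAM_LEVELS
    delta_levels: tuple[float, ...] = CLINICAL_DELTA_LEVELS
    n_agents: int = 150
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        for v in (*self.lam_levels, *self.delta_levels):
            if not 0.0 <= v <= 1.0:
                raise ValueError("parameter levels must lie in [0, 1]")


@dataclass
class CohortTable:
    """Long-format per-agent scores plus a per-cell mean/SD summary."""

    scores: pd.DataFrame
    summary: pd.DataFrame


def _agent_seed_seq(master: int, lam: float, delta: float) -> np.random.SeedSequence:
    # one substream family per cell, derived from the master seed
    return np.random.SeedSequence(
        [master, int(round(lam * 1000)), int(round(delta * 1000))]
    )


def simulate_cohort(
    lam: float,
    delta: float,
    n_agents: int,
    config: TaskConfig | None = None,
    seed: int = 0,
) -> list[Session]:
    """Simulate ``n_agents`` independent sessions at one parameter cell."""
    config = config or TaskConfig()
    params = AgentParams(lam=lam, delta=delta)
    children = _agent_seed_seq(seed, lam, delta).spawn(n_agents)
    return [run_agent(params, config, seed=np.random.default_rng(c)) for c in children]


def run_factorial(design: FactorialDesign | None = None) -> CohortTable:
    """Simulate and score every agent of a factorial design.

    The summary holds, per (lam, delta) cell and measure, the across-agent
    mean and standard deviation (NaN for single-agent cells).
    """
    design = design or FactorialDesign()
    rows = []
    for lam in design.lam_levels:
        for delta in design.delta_levels:
            sessions = simulate_cohort(
                lam, delta, design.n_agents, design.config, design.seed
            )
            for agent_id, session in enumerate(sessions):
                rep = score_session(session)
                rows.append(
                    {
                        "lam": lam,
                        "delta": delta,
                        "agent_id": agent_id,
                        "E": rep.nonperseverative_errors,
                        "PE": rep.perseverative_errors,
                        "TFC": rep.trials_to_first_category,
                        "TFC_censored": rep.tfc_censored,
                        "FMS": rep.failures_to_maintain_set,
                        "categories": rep.categories_completed,
                    }
                )
    scores = pd.DataFrame(rows)
    summary = (
        scores.groupby(["lam", "delta"])[list(MEASURES)]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") for c in summary.columns.to_flat_index()
    ]
    return CohortTable(scores=scores, summary=summary)


def run_info_dynamics(
    lam_levels: Sequence[float] = DYNAMICS_LEVELS,
    delta_levels: Sequence[float] = DYNAMICS_LEVELS,
    seed: int = 0,
    n_per_cell: int = 1,
    config: TaskConfig | None = None,
) -> dict[tuple[float, float], list[tuple[Session, InfoTrajectory]]]:
    """One (or more) full sessions per (lam, delta) cell with their
    Bayesian-surprise / Shannon-surprise / entropy series, for
    trajectory-panel figures."""
    config = config or TaskConfig()
    out: dict[tuple[float, float], list[tuple[Session, InfoTrajectory]]] = {}
    for lam in lam_levels:
        for delta in delta_levels:
            sessions = simulate_cohort(lam, delta, n_per_cell, config, seed)
            params = AgentParams(lam=lam, delta=delta)
            out[(lam, delta)] = [
                (s, reconstruct_trajectories(s, params)) for s in sessions
            ]
    return out


Sampler = Callable[[np.random.Generator], float]


def _as_sampler(spec: Sampler | tuple[float, float] | float) -> Sampler:
    if callable(spec):
        return spec
    if isinstance(spec, tuple):
        lo, hi = spec
        return lambda rng: float(rng.uniform(lo, hi))
    value = float(spec)
    return lambda rng: value


def synthetic_cohort(
    group_specs: Sequence[tuple[str, int, object, object]],
    seed: int = 0,
    config: TaskConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[Session]]]:
    """Simulate a multi-group cohort with per-individual parameters.

    Each spec is (name, n, lam_spec, delta_spec) where a spec is a constant,
    a (low, high) uniform range, or a callable rng -> float.  Returns a
    ground-truth table (group, individual, lam, delta) and the sessions per
    group — the raw material for end-to-end recovery and group-separation
    checks.
    """
    config = config or TaskConfig()
    root = np.random.SeedSequence(seed)
    truth_rows = []
    sessions: dict[str, list[Session]] = {}
    for g, (name, n, lam_spec, delta_spec) in enumerate(group_specs):
        lam_s, delta_s = _as_sampler(lam_spec), _as_sampler(delta_spec)
        sessions[name] = []
        children = np.random.SeedSequence([seed, g]).spawn(max(n, 1))
        for i in range(n):
            rng = np.random.default_rng(children[i])
            lam, delta = lam_s(rng), delta_s(rng)
            params = AgentParams(lam=lam, delta=delta)
            sessions[name].append(run_agent(params, config, seed=rng))
            truth_rows.append(
                {"group": name, "individual": i, "lam": lam, "delta": delta}
            )
    return pd.DataFrame(truth_rows), sessions
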