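"""Trajectory-panel figures for information-theoretic dynamics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agent import Session
from .info import InfoTrajectory

__all__ = ["plot_trajectories"]


def plot_trajectories(
    trajectory: InfoTrajectory,
    session: Session | None = None,
    ax: plt.Axes | None = None,
    title: str | None = None,
) -> plt.Axes:
    """Plot Bayesian surprise, Shannon surprise and predictive entropy over
    trials; error trials of the session (if given) are marked with ticks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = trajectory.trial
    ax.plot(t, trajectory.bayesian_surprise, label="Bayesian surprise", color="tab:blue")
    ax.plot(t, trajectory.shannon_surprise, label="Shannon surprise", color="tab:orange")
    ax.plot(t, trajectory.entropy, label="entropy", color="tab:green")
    if session is not None:
        errors = [rec.t for rec in session if rec.feedback == 0]
        ax.plot(errors, [-0.08] * len(errors), "|", color="black", label="errors")
    ax.set_xlabel("trial")
    ax.set_ylabel("nats")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    return ax
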