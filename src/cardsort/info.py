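"""Trial-by-trial information-theoretic measures of the agent's dynamics.

Three quantities, all in nats, summarise each trial:

* **Bayesian surprise** ``B_t`` — Kullback-Leibler divergence between the
  predictive distribution for the next trial and the one the current trial
  started from; the magnitude of belief updating.
* **Shannon surprise** ``I_t`` — negative log marginal probability of the
  observation under the current predictive distribution; its pure
  unexpectedness.
* **Predictive entropy** ``H_t`` — entropy of the predictive distribution;
  the agent's epistemic uncertainty about the active sorting rule.

Given fixed cognitive parameters, the belief recursion conditioned on an
observed (target, action, feedback) sequence is deterministic, so the whole
trajectory can be reconstructed from a session log — including sessions of
real participants once parameters have been estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .agent import AgentParams, Session, predictive_update, replay_beliefs, stability_matrix

__all__ = [
    "InfoTrajectory",
    "bayesian_surprise",
    "shannon_surprise",
    "predictive_entropy",
    "reconstruct_trajectories",
]


@dataclass
class InfoTrajectory:
    """Aligned per-trial series; index t matches the session's trials."""

    trial: np.ndarray
    bayesian_surprise: np.ndarray
    shannon_surprise: np.ndarray
    entropy: np.ndarray

    def __len__(self) -> int:
        return len(self.trial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "B": self.bayesian_surprise,
                "I": self.shannon_surprise,
                "H": self.entropy,
            }
        )


def bayesian_surprise(predictive_next: np.ndarray, prior_current: np.ndarray) -> float:
    """KL[p(s_{t+1} | x_{0:t}) || p(s_t | x_{0:t-1})] in nats.

    Computed between successive predictive distributions; the activation
    floor keeps the reference distribution strictly positive, so the
    divergence is finite (0 log 0 := 0).
    """
    return float(rel_entr(np.asarray(predictive_next, float),
                          np.asarray(prior_current, float)).sum())


def shannon_surprise(marginal: float) -> float:
    """-log p(x_t | x_{0:t-1}) in nats; ``marginal`` comes from the Bayes
    normalisation constant of the posterior update."""
    if not 0.0 < marginal <= 1.0 + 1e-12:
        raise ValueError(f"observation marginal must lie in (0, 1], got {marginal}")
    return float(-np.log(marginal))


def predictive_entropy(predictive: np.ndarray) -> float:
    """Shannon entropy of the predictive distribution in nats, in [0, ln 3]."""
    p = np.asarray(predictive, float)
    nz = p[p > 0.0]
    return float(-(nz * np.log(nz)).sum())


def reconstruct_trajectories(session: Session, params: AgentParams) -> InfoTrajectory:
    """Replay the belief recursion on an observed session and emit the three
    information series.

    Applied to a simulated session with its generating parameters this
    reproduces the quantities logged during simulation exactly, because the
    recursion conditioned on (a_t, f_t) is deterministic.
    """
    trials, bs, ss, hs = [], [], [], []
    for rec, belief, _q in replay_beliefs(params, session):
        predictive_next = predictive_update(
            belief.posterior, stability_matrix(belief.omega)
        )
        trials.append(rec.t)
        bs.append(bayesian_surprise(predictive_next, belief.prior))
        ss.append(shannon_surprise(belief.marginal))
        hs.append(predictive_entropy(belief.prior))
    return InfoTrajectory(
        trial=np.asarray(trials),
        bayesian_surprise=np.asarray(bs),
        shannon_surprise=np.asarray(ss),
        entropy=np.asarray(hs),
    )
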