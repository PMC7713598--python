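"""The Bayesian cognitive agent.

The agent treats the three feature dimensions as hidden environmental
states s_t in {1: color, 2: shape, 3: number} and maintains a probability
distribution over them, updated recursively from observations
x_t = (a_t, f_t) -- the chosen stimulus card and the binary feedback.

One trial of the belief recursion:

1. an action is sampled from the predictive distribution p(s_t | x_{0:t-1})
   (the card matching the target on the sampled feature is chosen);
2. the posterior p(s_t | x_{0:t}) follows by Bayes' rule from a likelihood
   built out of the feature-match indicators of the chosen card;
3. a *matching signal* m_t (the match vector gated by feedback) drives the
   state-activation vector omega_t, governed by the two cognitive
   parameters: flexibility (lambda) scales how fast activation of
   non-implicated states decays after negative feedback, and information
   loss (delta) damps the evidence carried by the matching signal;
4. the activations define a row-stochastic stability matrix Gamma(t) whose
   diagonal is omega_t, and the Chapman-Kolmogorov step through Gamma(t)
   produces the predictive distribution for the next trial.

All belief quantities are plain length-3 numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .task import (
    WCST,
    Card,
    TaskConfig,
    card_for_feature,
    match_vector,
)

__all__ = [
    "AgentParams",
    "BeliefState",
    "TrialRecord",
    "Session",
    "ImpossibleObservationError",
    "observation_likelihood",
    "likelihood_from_match",
    "posterior_update",
    "matching_signal",
    "activation_update",
    "stability_matrix",
    "predictive_update",
    "action_probabilities",
    "sample_action",
    "run_agent",
    "replay_beliefs",
]

UNIFORM = np.full(3, 1.0 / 3.0)

#: Lower clamp on predictive probabilities.  At parameter extremes the
#: activation dynamics produce exactly degenerate predictives (e.g. delta=0
#: drives the confirmed activation to exactly 1), after which a single
#: disconfirming observation would have probability zero and the recursion
#: could not continue.  Keeping every state at tiny positive mass makes all
#: observations possible while perturbing beliefs only at the 1e-12 level.
PREDICTIVE_FLOOR = 1e-12


def _floor_simplex(p: np.ndarray) -> np.ndarray:
    p = np.maximum(p, PREDICTIVE_FLOOR)
    return p / p.sum()


class ImpossibleObservationError(ValueError):
    """An observation has probability zero under the current belief state.

    With lapse = 0 the agent's action model puts no mass on cards that match
    the target on no feature, and positive feedback for such a card is
    inconsistent with any rule.  When fitting observed (human) data, set a
    positive lapse rate so every response keeps positive probability.
    """


@dataclass(frozen=True)
class AgentParams:
    """Cognitive parameters of the agent.

    lam: flexibility, in [0, 1] -- efficiency of disengaging attention from
        the currently active state after negative feedback.
    delta: information loss, in [0, 1] -- damping of the evidence conveyed
        by the matching signal; large values slow internal-model convergence.
    lapse: response-noise mixture weight in [0, 1): with this probability the
        response is uniform over the four cards.  0 for simulation; use a
        small positive value (0.01) when fitting observed human data.
    activation_floor: lower clamp on activations, keeping every state
        revivable (a literal zero is absorbing under the power-damping).
    gate_signal_on_feedback: if True (default, the literal reading of the
        matching-signal definition) m_t is the match vector on positive
        feedback and the zero vector on negative feedback; if False, m_t is
        the match vector regardless of feedback.
    """

    lam: float
    delta: float
    lapse: float = 0.0
    activation_floor: float = 1e-6
    gate_signal_on_feedback: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam (flexibility) must lie in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta (information loss) must lie in [0, 1]")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse must lie in [0, 1)")
        if self.activation_floor <= 0:
            raise ValueError("activation_floor must be positive")


@dataclass
class BeliefState:
    """Belief quantities attached to one trial.

    prior: predictive distribution p(s_t | x_{0:t-1}) the action was
        sampled from; posterior: p(s_t | x_{0:t}); omega: activation vector
    after the trial; marginal: p(x_t | x_{0:t-1}), consumed by Shannon
    surprise.  The stability matrix is derivable from omega and is not
    stored.
    """

    prior: np.ndarray
    posterior: np.ndarray
    omega: np.ndarray
    marginal: float

    def stability(self) -> np.ndarray:
        return stability_matrix(self.omega)


@dataclass
class TrialRecord:
    t: int
    target: Card
    action: int
    feedback: int
    match: np.ndarray
    true_rule: int | None = None
    sampled_feature: int | None = None
    belief: BeliefState | None = None


@dataclass
class Session:
    """An ordered trial log plus the configuration that produced it.

    ``params`` and ``seed`` are present for simulated sessions only.
    """

    trials: list[TrialRecord]
    config: TaskConfig = field(default_factory=TaskConfig)
    params: AgentParams | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def to_frame(self, beliefs: bool = False) -> pd.DataFrame:
        """Tabular view; with ``beliefs=True`` include per-trial prior,
        posterior and activation columns."""
        rows = []
        for rec in self.trials:
            row = {
                "trial": rec.t,
                "target_color": rec.target.color,
                "target_shape": rec.target.shape,
                "target_number": rec.target.number,
                "action": rec.action,
                "feedback": rec.feedback,
                "true_rule": rec.true_rule,
            }
            if beliefs and rec.belief is not None:
                for i in range(3):
                    row[f"prior_{i + 1}"] = rec.belief.prior[i]
                    row[f"post_{i + 1}"] = rec.belief.posterior[i]
                    row[f"omega_{i + 1}"] = rec.belief.omega[i]
                row["marginal"] = rec.belief.marginal
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Belief recursion primitives
# ---------------------------------------------------------------------------

def likelihood_from_match(match: np.ndarray, feedback: int) -> np.ndarray:
    """Observation likelihood vector over the three states from a match
    vector and feedback.

    Component i is
    [f * match_i + (1-f) * (1-match_i)] / [f * sum(match) + (1-f) * sum(1-match)]:
    positive feedback spreads mass over the matching features, negative
    feedback over the non-matching ones.  The common denominator cancels in
    the posterior but fixes the scale of the observation marginal.
    """
    match = np.asarray(match, dtype=float)
    numer = match if feedback else 1.0 - match
    denom = numer.sum()
    if denom == 0.0:
        raise ImpossibleObservationError(
            "positive feedback for a card matching the target on no feature"
        )
    return numer / denom


def observation_likelihood(target: Card, action: int, feedback: int) -> np.ndarray:
    """Likelihood vector for choosing stimulus card ``action`` on ``target``
    and receiving ``feedback``."""
    return likelihood_from_match(match_vector(target, action), feedback)


def posterior_update(
    prior: np.ndarray, likelihood: np.ndarray
) -> tuple[np.ndarray, float]:
    """Bayes step: posterior ∝ likelihood * prior; also returns the
    observation marginal p(x_t | x_{0:t-1}) = sum(likelihood * prior)."""
    weighted = np.asarray(likelihood, dtype=float) * np.asarray(prior, dtype=float)
    marginal = float(weighted.sum())
    if marginal <= 0.0:
        raise ImpossibleObservationError(
            "observation has zero probability under the current prior; "
            "use a positive lapse rate when fitting observed data"
        )
    return weighted / marginal, marginal


def matching_signal(
    match: np.ndarray, feedback: int, gate_on_feedback: bool = True
) -> np.ndarray:
    """Matching signal m_t: which features the feedback implicates.

    Default semantics: the match vector on positive feedback, the zero
    vector otherwise.  With ``gate_on_feedback=False`` the match vector is
    passed through regardless of feedback (alternative reading kept for
    sensitivity analysis).
    """
    match = np.asarray(match, dtype=float)
    if gate_on_feedback and not feedback:
        return np.zeros(3)
    return match.astype(float)


def activation_update(
    omega_prev: np.ndarray,
    m: np.ndarray,
    feedback: int,
    params: AgentParams,
) -> np.ndarray:
    """One step of the state-activation dynamics.

    omega_t = f * omega_{t-1}^delta * m
              + lambda * [(1-f) * omega_{t-1}^delta * (1-m)] * omega_{t-1},
    elementwise, clamped below at the activation floor.  On positive
    feedback the implicated states are re-activated at a level damped by
    delta and all others collapse; on negative feedback the activation of
    non-implicated states decays at a rate set by flexibility.
    """
    omega_prev = np.asarray(omega_prev, dtype=float)
    m = np.asarray(m, dtype=float)
    damped = omega_prev**params.delta
    f = float(feedback)
    omega = f * damped * m + params.lam * ((1.0 - f) * damped * (1.0 - m)) * omega_prev
    return np.maximum(omega, params.activation_floor)


def stability_matrix(omega: np.ndarray) -> np.ndarray:
    """Row-stochastic stability matrix: diagonal omega_i, off-diagonal
    (1 - omega_i) / 2.  Row i encodes the believed persistence of state i
    versus a symmetric switch to the other two states."""
    omega = np.asarray(omega, dtype=float)
    gamma = np.empty((3, 3))
    for i in range(3):
        gamma[i] = (1.0 - omega[i]) / 2.0
        gamma[i, i] = omega[i]
    return gamma


def predictive_update(posterior: np.ndarray, stability: np.ndarray) -> np.ndarray:
    """Chapman-Kolmogorov step: predictive_k = sum_i Gamma_ik * posterior_i."""
    return np.asarray(posterior, dtype=float) @ np.asarray(stability, dtype=float)


def action_probabilities(
    predictive: np.ndarray, target: Card, lapse: float = 0.0
) -> np.ndarray:
    """Model-implied distribution q(a) over the four stimulus cards.

    q(a) = (1 - lapse) * sum_i predictive_i * 1[card_for_feature(target, i) = a]
           + lapse / 4.
    """
    q = np.full(4, lapse / 4.0)
    for i in range(3):
        q[card_for_feature(target, i + 1) - 1] += (1.0 - lapse) * predictive[i]
    return q


def sample_action(
    predictive: np.ndarray,
    target: Card,
    rng: np.random.Generator,
    lapse: float = 0.0,
) -> tuple[int, int]:
    """Sample (feature, action): feature ~ predictive, action the stimulus
    card matching the target on that feature; with probability ``lapse`` the
    action is instead uniform over the four cards (the sampled feature is
    still recorded)."""
    u = rng.random()
    cum = np.cumsum(predictive)
    feature = int(np.searchsorted(cum, u * cum[-1], side="right")) + 1
    feature = min(feature, 3)
    if lapse > 0.0 and rng.random() < lapse:
        action = int(rng.integers(1, 5))
    else:
        action = card_for_feature(target, feature)
    return feature, action


# ---------------------------------------------------------------------------
# Generative loop and conditional replay
# ---------------------------------------------------------------------------

def run_agent(
    params: AgentParams,
    config: TaskConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> Session:
    """Simulate a full WCST session.

    Initialisation: omega_0 = (0.5, 0.5, 0.5), uniform prior over states.
    Per trial: draw a target, sample an action from the predictive
    distribution, obtain feedback from the protocol, then run the belief
    recursion (posterior, activations, stability, predictive).  Belief
    snapshots are attached to every trial record.
    """
    config = config or TaskConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = WCST(config, rng)

    omega = np.full(3, 0.5)
    prior = UNIFORM.copy()
    trials: list[TrialRecord] = []

    while not env.state.done:
        t = env.state.t + 1
        rule = env.current_rule
        target = env.next_target()
        feature, action = sample_action(prior, target, rng, params.lapse)
        feedback = env.step(target, action)
        match = match_vector(target, action)

        posterior, marginal = posterior_update(
            prior, likelihood_from_match(match, feedback)
        )
        m = matching_signal(match, feedback, params.gate_signal_on_feedback)
        omega = activation_update(omega, m, feedback, params)
        predictive = _floor_simplex(
            predictive_update(posterior, stability_matrix(omega))
        )

        trials.append(
            TrialRecord(
                t=t,
                target=target,
                action=action,
                feedback=feedback,
                match=match,
                true_rule=rule,
                sampled_feature=feature,
                belief=BeliefState(
                    prior=prior, posterior=posterior, omega=omega.copy(), marginal=marginal
                ),
            )
        )
        prior = predictive

    return Session(
        trials=trials,
        config=config,
        params=params,
        seed=seed if isinstance(seed, int) else None,
    )


def replay_beliefs(
    params: AgentParams, trials: Iterable[TrialRecord]
) -> Iterator[tuple[TrialRecord, BeliefState, float]]:
    """Replay the deterministic belief recursion conditioned on an observed
    (target, action, feedback) sequence.

    Yields (record, belief, q_action) per trial, where q_action is the
    model-implied probability of the observed action given the history --
    the per-trial likelihood factor used for parameter estimation.  Raises
    :class:`ImpossibleObservationError` on a zero-probability action when
    ``params.lapse`` is 0.
    """
    omega = np.full(3, 0.5)
    prior = UNIFORM.copy()
    for rec in trials:
        q = action_probabilities(prior, rec.target, params.lapse)[rec.action - 1]
        if q <= 0.0:
            raise ImpossibleObservationError(
                f"trial {rec.t}: observed action {rec.action} has zero "
                "probability; set lapse > 0 to fit this session"
            )
        match = (
            rec.match
            if rec.match is not None
            else match_vector(rec.target, rec.action)
        )
        posterior, marginal = posterior_update(
            prior, likelihood_from_match(match, rec.feedback)
        )
        m = matching_signal(match, rec.feedback, params.gate_signal_on_feedback)
        omega = activation_update(omega, m, rec.feedback, params)
        belief = BeliefState(
            prior=prior, posterior=posterior, omega=omega.copy(), marginal=marginal
        )
        yield rec, belief, float(q)
        prior = _floor_simplex(predictive_update(posterior, stability_matrix(omega)))
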