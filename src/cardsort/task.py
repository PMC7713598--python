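"""Deterministic Wisconsin Card Sorting Test (WCST) environment.

The WCST confronts a participant with a *target card* on every trial, to be
matched against one of four fixed *stimulus cards*.  Cards carry three
categorical features -- color, shape and number of objects, each with four
levels -- and only one feature (the hidden *sorting rule*) determines whether
a match is correct.  Feedback is binary.  Under the Heaton administration
protocol the rule changes silently after a fixed run of consecutive correct
responses (10 by default).

This module contains only the task side of the problem: cards, the target
deck, feature matching, feedback, and the deterministic rule schedule.  The
cognitive agent that plays the task lives in :mod:`cardsort.agent`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Card",
    "TaskConfig",
    "TaskState",
    "WCST",
    "COLOR",
    "SHAPE",
    "NUMBER",
    "FEATURE_NAMES",
    "STIMULUS_DECK",
    "build_stimulus_deck",
    "all_cards",
    "nonstimulus_cards",
    "draw_target",
    "match_vector",
    "card_for_feature",
    "give_feedback",
    "advance_rule",
]

#: Feature dimensions (1-based, matching the hidden-state indexing).
COLOR, SHAPE, NUMBER = 1, 2, 3
FEATURE_NAMES = ("color", "shape", "number")
COLOR_NAMES = ("red", "green", "blue", "yellow")
SHAPE_NAMES = ("triangle", "star", "cross", "circle")


class Card(NamedTuple):
    """A WCST card: feature levels are categorical codes in 1..4.

    color: 1=red, 2=green, 3=blue, 4=yellow
    shape: 1=triangle, 2=star, 3=cross, 4=circle
    number: number of depicted objects, 1..4
    """

    color: int
    shape: int
    number: int

    def feature(self, dim: int) -> int:
        """Value of feature dimension ``dim`` (1=color, 2=shape, 3=number)."""
        return self[dim - 1]

    def describe(self) -> str:
        return f"{COLOR_NAMES[self.color - 1]} {SHAPE_NAMES[self.shape - 1]} x{self.number}"


def build_stimulus_deck() -> tuple[Card, Card, Card, Card]:
    """The four canonical WCST stimulus cards.

    (red triangle x1, green star x2, yellow cross x3, blue circle x4): the
    cards are pairwise distinct on *every* dimension, so any target card
    matches exactly one stimulus card per feature dimension.
    """
    return (Card(1, 1, 1), Card(2, 2, 2), Card(4, 3, 3), Card(3, 4, 4))


STIMULUS_DECK = build_stimulus_deck()

# value -> stimulus-card index (1..4), one table per feature dimension;
# well defined because the deck is pairwise distinct on every dimension
_CARD_BY_FEATURE: tuple[dict[int, int], ...] = tuple(
    {STIMULUS_DECK[k][dim]: k + 1 for k in range(4)} for dim in range(3)
)


def all_cards() -> list[Card]:
    """All 64 feature combinations."""
    return [Card(*f) for f in itertools.product(range(1, 5), repeat=3)]


def nonstimulus_cards() -> list[Card]:
    """The 60 combinations that are not identical to a stimulus card.

    Cards identical to a stimulus card would match it on all three
    dimensions, which yields feedback uninformative about the rule; the
    default target deck excludes them.
    """
    deck = set(STIMULUS_DECK)
    return [c for c in all_cards() if c not in deck]


_NONSTIMULUS = tuple(nonstimulus_cards())
_ALL = tuple(all_cards())


def match_vector(target: Card, action: int) -> np.ndarray:
    """Binary 3-vector: entry i is 1 iff stimulus card ``action`` equals
    ``target`` on feature dimension i+1."""
    chosen = STIMULUS_DECK[action - 1]
    return np.array(
        [int(chosen[d] == target[d]) for d in range(3)], dtype=np.int8
    )


def card_for_feature(target: Card, feature: int) -> int:
    """Index (1..4) of the unique stimulus card matching ``target`` on
    ``feature``; inverse of :func:`match_vector` along one dimension."""
    return _CARD_BY_FEATURE[feature - 1][target[feature - 1]]


def give_feedback(target: Card, action: int, true_rule: int) -> int:
    """Examiner feedback: 1 iff the chosen card matches the target on the
    currently valid sorting rule."""
    return int(match_vector(target, action)[true_rule - 1])


@dataclass(frozen=True)
class TaskConfig:
    """Administration protocol parameters.

    max_trials: session length cap (Heaton: 128).
    consecutive_to_complete: correct responses in a row that complete a
        category and silently advance the rule (Heaton: 10).
    max_categories: stop after this many completed categories (``None`` =
        unbounded; the clinical application protocol uses 6).
    rule_sequence: cyclic order of the hidden rules; canonical Heaton cycle
        is color -> shape -> number.
    deck_policy: "uniform-60" (default; uniform over the 60 targets not
        identical to a stimulus card), "uniform-64", or "fixed-list".
    fixed_targets: explicit target ordering for deck_policy="fixed-list".
    """

    max_trials: int = 128
    consecutive_to_complete: int = 10
    max_categories: int | None = None
    rule_sequence: tuple[int, ...] = (COLOR, SHAPE, NUMBER)
    deck_policy: str = "uniform-60"
    fixed_targets: tuple[Card, ...] | None = None

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        if self.consecutive_to_complete < 1:
            raise ValueError("consecutive_to_complete must be >= 1")
        if self.max_categories is not None and self.max_categories < 1:
            raise ValueError("max_categories must be >= 1 or None")
        if not self.rule_sequence or any(
            r not in (1, 2, 3) for r in self.rule_sequence
        ):
            raise ValueError("rule_sequence entries must be in {1, 2, 3}")
        if self.deck_policy not in ("uniform-60", "uniform-64", "fixed-list"):
            raise ValueError(f"unknown deck_policy {self.deck_policy!r}")
        if self.deck_policy == "fixed-list" and not self.fixed_targets:
            raise ValueError("fixed-list deck_policy requires fixed_targets")


@dataclass(frozen=True)
class TaskState:
    """Protocol bookkeeping: current rule position, correct streak,
    categories completed and termination flag.  Trials are 1-based."""

    t: int = 0
    rule_pos: int = 0
    streak: int = 0
    categories: int = 0
    done: bool = False

    def rule(self, config: TaskConfig) -> int:
        return config.rule_sequence[self.rule_pos % len(config.rule_sequence)]


def draw_target(
    rng: np.random.Generator,
    deck_policy: str = "uniform-60",
    fixed_targets: Sequence[Card] | None = None,
    t: int | None = None,
) -> Card:
    """Draw the next target card under the configured deck policy."""
    if deck_policy == "uniform-60":
        return _NONSTIMULUS[rng.integers(len(_NONSTIMULUS))]
    if deck_policy == "uniform-64":
        return _ALL[rng.integers(len(_ALL))]
    if deck_policy == "fixed-list":
        if fixed_targets is None or t is None or t > len(fixed_targets):
            raise ValueError(
                "fixed-list deck exhausted or not supplied "
                f"(trial {t}, list length {0 if fixed_targets is None else len(fixed_targets)})"
            )
        return fixed_targets[t - 1]
    raise ValueError(f"unknown deck_policy {deck_policy!r}")


def advance_rule(state: TaskState, feedback: int, config: TaskConfig) -> TaskState:
    """Advance the protocol after a trial with the given feedback.

    The correct-streak counter increments on positive feedback and resets on
    any error.  When it reaches ``consecutive_to_complete`` the category is
    complete: the rule advances cyclically, the counter resets, and the
    session terminates if ``max_categories`` is reached.  Trial-count
    termination is applied as well.
    """
    t = state.t + 1
    streak = state.streak + 1 if feedback else 0
    rule_pos, categories = state.rule_pos, state.categories
    if streak == config.consecutive_to_complete:
        rule_pos += 1
        categories += 1
        streak = 0
    done = t >= config.max_trials or (
        config.max_categories is not None and categories >= config.max_categories
    )
    return TaskState(t=t, rule_pos=rule_pos, streak=streak, categories=categories, done=done)


class WCST:
    """Stateful wrapper around the pure protocol functions.

    Typical use::

        env = WCST(TaskConfig(), np.random.default_rng(0))
        while not env.state.done:
            target = env.next_target()
            action = ...            # agent's choice, 1..4
            feedback = env.step(target, action)
    """

    def __init__(self, config: TaskConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.state = TaskState()

    @property
    def current_rule(self) -> int:
        return self.state.rule(self.config)

    def next_target(self) -> Card:
        return draw_target(
            self.rng,
            self.config.deck_policy,
            self.config.fixed_targets,
            t=self.state.t + 1,
        )

    def step(self, target: Card, action: int) -> int:
        """Apply an action; returns feedback and advances the protocol."""
        if self.state.done:
            raise RuntimeError("session already terminated")
        feedback = give_feedback(target, action, self.current_rule)
        self.state = advance_rule(self.state, feedback, self.config)
        return feedback
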