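"""Heaton-style neuropsychological scoring of WCST sessions.

Four standard indices are computed from a trial log:

* total / perseverative (PE) / non-perseverative (E) errors,
* trials to complete the first category (TFC),
* failures to maintain set (FMS).

A *perseverative* error is a response consistent with the sorting rule that
was valid before the most recent rule change -- the participant keeps
sorting by the old principle.  A *failure to maintain set* is an error made
after the current rule has demonstrably been acquired (at least five
consecutive correct responses) but before the category is complete,
conventionally attributed to distractibility.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from .agent import Session

__all__ = [
    "ScoreReport",
    "classify_errors",
    "trials_to_first_category",
    "failures_to_maintain_set",
    "score_session",
]

CORRECT, PE, E = "correct", "PE", "E"


@dataclass(frozen=True)
class ScoreReport:
    """Summary scores of one session."""

    total_errors: int
    perseverative_errors: int
    nonperseverative_errors: int
    trials_to_first_category: int
    tfc_censored: bool
    failures_to_maintain_set: int
    categories_completed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _require_rules(session: Session) -> None:
    if any(rec.true_rule is None for rec in session):
        raise ValueError(
            "session lacks rule annotations; reconstruct them from the "
            "feedback stream first (see inference.annotate_rules)"
        )


def classify_errors(session: Session, sandwich: bool = False) -> list[str]:
    """Per-trial labels in {'correct', 'PE', 'E'}.

    An error is perseverative when the chosen card matches the target on the
    *perseverated-to principle* -- the rule in force before the most recent
    rule change -- and that match is unambiguous (the card matches the
    target on exactly that one dimension).  Errors before the first rule
    change, and ambiguous errors, count as non-perseverative.  With
    ``sandwich=True``, an ambiguous error that matches the perseverated-to
    principle and is flanked by two perseverative errors is relabelled PE
    (optional stricter scoring convention; off by default).
    """
    _require_rules(session)
    n_consec = session.config.consecutive_to_complete

    labels: list[str] = []
    prev_rule: int | None = None  # perseverated-to principle
    streak = 0
    ambiguous_candidate: list[bool] = []
    for rec in session:
        if rec.feedback:
            streak += 1
            labels.append(CORRECT)
            ambiguous_candidate.append(False)
            if streak == n_consec:
                prev_rule = rec.true_rule
                streak = 0
            continue
        streak = 0
        if prev_rule is not None and rec.match[prev_rule - 1] == 1:
            if int(rec.match.sum()) == 1:
                labels.append(PE)
                ambiguous_candidate.append(False)
            else:
                labels.append(E)
                ambiguous_candidate.append(True)
        else:
            labels.append(E)
            ambiguous_candidate.append(False)

    if sandwich:
        error_pos = [i for i, lab in enumerate(labels) if lab != CORRECT]
        for k, i in enumerate(error_pos):
            if (
                ambiguous_candidate[i]
                and 0 < k < len(error_pos) - 1
                and labels[error_pos[k - 1]] == PE
                and labels[error_pos[k + 1]] == PE
            ):
                labels[i] = PE
    return labels


def trials_to_first_category(session: Session) -> tuple[int, bool]:
    """Index of the trial completing the first run of
    ``consecutive_to_complete`` correct responses; censored at the session
    length (flag True) when the first category is never completed."""
    n_consec = session.config.consecutive_to_complete
    streak = 0
    for rec in session:
        streak = streak + 1 if rec.feedback else 0
        if streak == n_consec:
            return rec.t, False
    return len(session), True


def failures_to_maintain_set(session: Session) -> int:
    """Count errors directly following >= 5 consecutive correct responses
    under the same (still current) rule.

    The acquisition streak is tracked per rule: it resets on errors and at
    category completion, so the first errors after a silent rule change are
    perseveration-type, not set-maintenance failures.
    """
    _require_rules(session)
    n_consec = session.config.consecutive_to_complete
    fms = 0
    streak = 0
    for rec in session:
        if rec.feedback:
            streak += 1
            if streak == n_consec:
                streak = 0  # category complete; rule changes silently
        else:
            if streak >= 5:
                fms += 1
            streak = 0
    return fms


def categories_completed(session: Session) -> int:
    n_consec = session.config.consecutive_to_complete
    done = 0
    streak = 0
    for rec in session:
        streak = streak + 1 if rec.feedback else 0
        if streak == n_consec:
            done += 1
            streak = 0
    return done


def score_session(session: Session, sandwich: bool = False) -> ScoreReport:
    """Aggregate the four Heaton-style indices for one session."""
    labels = classify_errors(session, sandwich=sandwich)
    pe = labels.count(PE)
    e = labels.count(E)
    tfc, censored = trials_to_first_category(session)
    return ScoreReport(
        total_errors=pe + e,
        perseverative_errors=pe,
        nonperseverative_errors=e,
        trials_to_first_category=tfc,
        tfc_censored=censored,
        failures_to_maintain_set=failures_to_maintain_set(session),
        categories_completed=categories_completed(session),
    )
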