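"""Heaton-style clinical scoring on constructed and simulated sessions."""

import numpy as np
import pytest

from cardsort.agent import AgentParams, Session, TrialRecord, run_agent
from cardsort.scoring import (
    classify_errors,
    failures_to_maintain_set,
    score_session,
    trials_to_first_category,
)
from cardsort.task import Card, TaskConfig, card_for_feature, match_vector

#: A target matching a distinct stimulus card on every dimension.
TARGET = Card(3, 2, 1)  # color -> card 4, shape -> card 2, number -> card 1


def build_session(script, config=None):
    """Construct a session from a script of (rule, action_feature) pairs.

    ``action_feature`` is the feature dimension the simulated respondent
    sorts by on that trial; feedback follows from the rule.  Using a target
    whose three matching cards are distinct keeps every response
    unambiguous.
    """
    config = config or TaskConfig()
    trials = []
    for t, (rule, feature) in enumerate(script, start=1):
        action = card_for_feature(TARGET, feature)
        match = match_vector(TARGET, action)
        trials.append(
            TrialRecord(
                t=t,
                target=TARGET,
                action=action,
                feedback=int(match[rule - 1]),
                match=match,
                true_rule=rule,
            )
        )
    return Session(trials=trials, config=config)


def heaton_script(*segments):
    """Flatten (rule, feature, repeats) segments into a script."""
    out = []
    for rule, feature, n in segments:
        out.extend([(rule, feature)] * n)
    return out


class TestTrialsToFirstCategory:
    def test_immediate_completion(self):
        s = build_session(heaton_script((1, 1, 10), (2, 2, 5)))
        assert trials_to_first_category(s) == (10, False)

    def test_error_resets_run(self):
        # 6 correct, 1 error, then 10 consecutive correct -> completes at 17
        s = build_session(heaton_script((1, 1, 6), (1, 2, 1), (1, 1, 10)))
        assert trials_to_first_category(s) == (17, False)

    def test_censored_when_never_completed(self):
        s = build_session([(1, 2)] * 30)
        assert trials_to_first_category(s) == (30, True)


class TestFailuresToMaintainSet:
    def test_error_after_six_correct_counts(self):
        s = build_session(heaton_script((1, 1, 6), (1, 2, 1), (1, 1, 10)))
        assert failures_to_maintain_set(s) == 1

    def test_set_not_acquired_below_five(self):
        s = build_session(heaton_script((1, 1, 4), (1, 2, 1), (1, 1, 10)))
        assert failures_to_maintain_set(s) == 0

    def test_post_change_errors_are_not_fms(self):
        # completed category, then persistence errors under the new rule
        s = build_session(heaton_script((1, 1, 10), (2, 1, 3), (2, 2, 10)))
        assert failures_to_maintain_set(s) == 0

    def test_perfect_agent_has_none(self):
        s = build_session(heaton_script((1, 1, 10), (2, 2, 10), (3, 3, 10)))
        assert failures_to_maintain_set(s) == 0


class TestErrorClassification:
    def test_perseveration_to_previous_rule(self):
        # color category completed; agent keeps sorting by color under shape
        s = build_session(heaton_script((1, 1, 10), (2, 1, 2), (2, 2, 10)))
        labels = classify_errors(s)
        assert labels[10] == "PE" and labels[11] == "PE"

    def test_errors_before_first_change_are_nonperseverative(self):
        s = build_session(heaton_script((1, 2, 3), (1, 1, 10)))
        assert classify_errors(s)[:3] == ["E", "E", "E"]

    def test_ambiguous_match_on_old_rule_is_nonperseverative(self):
        """An error matching the old rule on more than one dimension stays
        a casual error under the default (sandwich off)."""
        # target red star x2 matches card 2 on shape AND number
        ambiguous = Card(1, 2, 2)
        cfg = TaskConfig()
        trials = []
        for t in range(1, 11):  # complete the shape category unambiguously
            action = card_for_feature(TARGET, 2)
            trials.append(
                TrialRecord(t=t, target=TARGET, action=action,
                            feedback=1, match=match_vector(TARGET, action),
                            true_rule=2)
            )
        # now rule = color; respond by shape on the ambiguous target
        action = card_for_feature(ambiguous, 2)
        match = match_vector(ambiguous, action)
        assert match.sum() == 2  # shape + number
        trials.append(
            TrialRecord(t=11, target=ambiguous, action=action,
                        feedback=int(match[0]), match=match, true_rule=1)
        )
        s = Session(trials=trials, config=cfg)
        assert classify_errors(s)[10] == "E"
        # the sandwich option only upgrades when flanked by two PEs
        assert classify_errors(s, sandwich=True)[10] == "E"

    def test_third_rule_error_after_change_is_nonperseverative(self):
        s = build_session(heaton_script((1, 1, 10), (2, 3, 1), (2, 2, 10)))
        assert classify_errors(s)[10] == "E"

    def test_missing_rule_annotations_raise(self, example_session):
        import copy

        s = copy.deepcopy(example_session)
        for rec in s:
            rec.true_rule = None
        with pytest.raises(ValueError, match="rule annotations"):
            classify_errors(s)


class TestScoreSession:
    def test_perfect_session_report(self):
        s = build_session(
            heaton_script((1, 1, 10), (2, 2, 10), (3, 3, 10))
        )
        rep = score_session(s)
        assert rep.total_errors == 0
        assert rep.perseverative_errors == 0
        assert rep.failures_to_maintain_set == 0
        assert rep.trials_to_first_category == 10
        assert not rep.tfc_censored
        assert rep.categories_completed == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_error_partition_and_bounds_on_simulated_sessions(self, seed):
        s = run_agent(AgentParams(0.4, 0.6), seed=seed)
        rep = score_session(s)
        assert (
            rep.perseverative_errors + rep.nonperseverative_errors
            == rep.total_errors
        )
        assert rep.trials_to_first_category <= len(s)
        assert rep.failures_to_maintain_set >= 0

    def test_determinism(self, example_session):
        assert score_session(example_session) == score_session(example_session)
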