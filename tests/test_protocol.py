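"""Interaction-flow state machine: transitions, guards, safety, replay."""

import random

import pytest

from sleepcoach.instruments import Occasion, classify_isi
from sleepcoach.protocol import (
    EventKind,
    ProtocolEvent,
    ProtocolState,
    ProtocolViolation,
    Stage,
    TERMINAL_STAGES,
    advance,
    funnel_counts,
    replay,
    state_from_dict,
    state_to_dict,
    transition_table,
)

from conftest import build_entry


def isi_event(total: int, occasion: Occasion) -> ProtocolEvent:
    return ProtocolEvent(EventKind.ISI_COMPLETED, classify_isi(total, occasion=occasion))


def diary_event(i: int = 0) -> ProtocolEvent:
    return ProtocolEvent(EventKind.DIARY_ENTRY_VALIDATED, build_entry(660, 480, 30, 20, 10))


def run_to_step2(total1: int = 16, total2: int = 15):
    state = ProtocolState()
    state, _ = advance(state, isi_event(total1, Occasion.INTERVIEW1))
    for _ in range(7):
        state, _ = advance(state, diary_event())
    state, _ = advance(state, isi_event(total2, Occasion.INTERVIEW2))
    return state


class TestScreeningBranch:
    def test_low_total_gets_hygiene_and_terminates(self):
        state, actions = advance(ProtocolState(), isi_event(10, Occasion.INTERVIEW1))
        assert state.stage == Stage.SCREENED_LOW
        assert [a.template_id for a in actions] == [
            "advice.regular_wake_time",
            "advice.morning_light",
            "advice.quiet_dark_room",
        ]
        with pytest.raises(ProtocolViolation):
            advance(state, diary_event())

    def test_eligible_total_enters_step1(self):
        state, actions = advance(ProtocolState(), isi_event(16, Occasion.INTERVIEW1))
        assert state.stage == Stage.STEP1_DIARY
        assert actions[0].template_id == "instruction.start_sleep_diary"

    def test_threshold_boundary(self):
        low, _ = advance(ProtocolState(), isi_event(14, Occasion.INTERVIEW1))
        high, _ = advance(ProtocolState(), isi_event(15, Occasion.INTERVIEW1))
        assert low.stage == Stage.SCREENED_LOW
        assert high.stage == Stage.STEP1_DIARY


class TestStep1Week:
    def test_seven_validated_entries_trigger_interview2(self):
        state, _ = advance(ProtocolState(), isi_event(16, Occasion.INTERVIEW1))
        for i in range(6):
            state, actions = advance(state, diary_event())
            assert state.stage == Stage.STEP1_DIARY
            assert actions[0].template_id == "feedback.morning"
        state, actions = advance(state, diary_event())
        assert state.stage == Stage.INTERVIEW2_DUE
        assert state.diary_days_done == 7
        assert actions[-1].template_id == "interview.request"
        assert actions[-1].param("occasion") == "interview2"

    def test_feedback_carries_derived_values(self):
        state, _ = advance(ProtocolState(), isi_event(16, Occasion.INTERVIEW1))
        _, actions = advance(state, diary_event())
        fb = actions[0]
        assert fb.param("tib_hhmm") == "08:00"
        assert fb.param("se") == "87.5"  # (480-60)/480

    def test_extra_diary_entries_welcome_while_interview_due(self):
        state = ProtocolState(stage=Stage.INTERVIEW2_DUE, diary_days_done=7)
        state, actions = advance(state, diary_event())
        assert state.stage == Stage.INTERVIEW2_DUE
        assert state.diary_days_done == 8


class TestStep2AndClosure:
    def test_ten_days_then_interview3(self):
        state = run_to_step2()
        assert state.stage == Stage.STEP2_ACTIVE
        for i in range(9):
            state, _ = advance(state, ProtocolEvent(EventKind.STEP2_DAY_ELAPSED))
            assert state.stage == Stage.STEP2_ACTIVE
        state, actions = advance(state, ProtocolEvent(EventKind.STEP2_DAY_ELAPSED))
        assert state.stage == Stage.INTERVIEW3_DUE
        assert state.step2_days_done == 10
        assert actions[-1].param("occasion") == "interview3"

    @pytest.mark.parametrize(
        "total3,expected_stage,expected_action",
        [
            (23, Stage.REFERRED, "referral.sleep_specialist"),
            (21, Stage.AUTONOMOUS_USE, "closure.autonomous_use"),
            (12, Stage.AUTONOMOUS_USE, "closure.autonomous_use"),
        ],
    )
    def test_interview3_branches_on_referral_threshold(
        self, total3, expected_stage, expected_action
    ):
        state = run_to_step2()
        for _ in range(10):
            state, _ = advance(state, ProtocolEvent(EventKind.STEP2_DAY_ELAPSED))
        state, actions = advance(state, isi_event(total3, Occasion.INTERVIEW3))
        assert state.stage == expected_stage
        assert actions[0].template_id == expected_action


class TestIllegalTransitions:
    def test_interview2_before_seven_diary_days(self):
        state, _ = advance(ProtocolState(), isi_event(16, Occasion.INTERVIEW1))
        for _ in range(5):
            state, _ = advance(state, diary_event())
        with pytest.raises(ProtocolViolation, match="step1_diary"):
            advance(state, isi_event(15, Occasion.INTERVIEW2))

    def test_wrong_occasion_rejected(self):
        with pytest.raises(ProtocolViolation, match="interview1"):
            advance(ProtocolState(), isi_event(16, Occasion.INTERVIEW2))

    def test_terminal_stages_absorbing(self):
        for stage in TERMINAL_STAGES:
            state = ProtocolState(stage=stage)
            with pytest.raises(ProtocolViolation):
                advance(state, ProtocolEvent(EventKind.USER_DROPOUT))

    def test_dropout_legal_from_non_terminal_stages(self):
        state = ProtocolState(stage=Stage.STEP2_ACTIVE, diary_days_done=7)
        new, actions = advance(state, ProtocolEvent(EventKind.USER_DROPOUT))
        assert new.stage == Stage.DROPPED_OUT
        assert actions == []

    def test_payload_type_checked(self):
        with pytest.raises(ValueError):
            ProtocolEvent(EventKind.ISI_COMPLETED, None)
        with pytest.raises(ValueError):
            ProtocolEvent(EventKind.USER_DROPOUT, classify_isi(5))


class TestTransitionTable:
    def test_every_intervention_stage_has_outgoing_edge(self):
        table = transition_table()
        sources = {t.stage for t in table}
        for stage in Stage:
            if stage in TERMINAL_STAGES:
                assert stage not in sources
            else:
                assert stage in sources

    def test_dropout_edge_from_every_non_terminal(self):
        table = transition_table()
        drops = {t.stage for t in table if t.event == EventKind.USER_DROPOUT}
        assert drops == {s for s in Stage if s not in TERMINAL_STAGES}


class TestSafetyModelCheck:
    EVENTS = [
        lambda rng: isi_event(rng.randint(0, 28), None),
        lambda rng: diary_event(),
        lambda rng: ProtocolEvent(EventKind.STEP2_DAY_ELAPSED),
        lambda rng: ProtocolEvent(EventKind.USER_DROPOUT),
    ]

    def _random_walk(self, rng, n_events=25):
        """Apply random events, ignoring illegal ones; invariants must hold
        after every accepted event."""
        state = ProtocolState()
        for _ in range(n_events):
            ev = rng.choice(self.EVENTS)(rng)
            if ev.kind == EventKind.ISI_COMPLETED:
                occ = (Occasion.INTERVIEW1, Occasion.INTERVIEW2, Occasion.INTERVIEW3)[
                    min(len(state.isi_history), 2)
                ]
                ev = isi_event(ev.payload.total, occ)
            try:
                state, _ = advance(state, ev)
            except ProtocolViolation:
                if state.stage in TERMINAL_STAGES:
                    break
                continue
            if state.stage in (Stage.STEP2_ACTIVE, Stage.INTERVIEW3_DUE):
                assert state.diary_days_done >= 7
            assert len(state.isi_history) <= 3
            occasions = [r.occasion for r in state.isi_history]
            assert occasions == sorted(occasions, key=lambda o: o.index)
        return state

    def test_randomized_event_sequences_respect_guards(self):
        rng = random.Random(20240423)
        for _ in range(1500):
            self._random_walk(rng)

    def test_replay_reproduces_final_state(self):
        events = [isi_event(17, Occasion.INTERVIEW1)] + [diary_event()] * 7 + [
            isi_event(15, Occasion.INTERVIEW2)
        ] + [ProtocolEvent(EventKind.STEP2_DAY_ELAPSED)] * 10 + [
            isi_event(13, Occasion.INTERVIEW3)
        ]
        s1, a1 = replay(events)
        s2, a2 = replay(events)
        assert s1 == s2
        assert a1 == a2
        assert s1.stage == Stage.AUTONOMOUS_USE


class TestFunnel:
    def test_empty_cohort(self):
        assert funnel_counts([]) == {
            "downloaded": 0,
            "screened": 0,
            "eligible": 0,
            "step1_completed": 0,
            "step2_completed": 0,
        }

    def test_single_completer_counts_every_upstream_stage(self):
        state = run_to_step2()
        for _ in range(10):
            state, _ = advance(state, ProtocolEvent(EventKind.STEP2_DAY_ELAPSED))
        state, _ = advance(state, isi_event(12, Occasion.INTERVIEW3))
        counts = funnel_counts([state])
        assert counts == {
            "downloaded": 1,
            "screened": 1,
            "eligible": 1,
            "step1_completed": 1,
            "step2_completed": 1,
        }

    def test_counts_monotone_on_mixed_cohort(self):
        states = [
            ProtocolState(),  # downloaded only
            advance(ProtocolState(), isi_event(10, Occasion.INTERVIEW1))[0],
            advance(ProtocolState(), isi_event(16, Occasion.INTERVIEW1))[0],
            run_to_step2(),
        ]
        counts = funnel_counts(states)
        values = [counts[k] for k in ("downloaded", "screened", "eligible", "step1_completed", "step2_completed")]
        assert values == sorted(values, reverse=True)
        assert values[0] == 4 and values[1] == 3 and values[2] == 2


def test_session_serialization_round_trip():
    state = run_to_step2(total1=19, total2=16)
    doc = state_to_dict(state)
    back = state_from_dict(doc)
    assert back.stage == state.stage
    assert back.diary_days_done == state.diary_days_done
    assert [r.total for r in back.isi_history] == [r.total for r in state.isi_history]
    assert [r.occasion for r in back.isi_history] == [r.occasion for r in state.isi_history]
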