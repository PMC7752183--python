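"""Interaction-flow state machine for the two-step insomnia program.

The flow: a screening interview (ISI, Interview 1) either ends with generic
sleep-hygiene advice (total <= 14) or admits the user to the intervention;
Step 1 is a 7-day electronic sleep diary with morning feedback, after which
a follow-up interview (Interview 2) re-administers the ISI; Step 2 delivers
personalized recommendations for 10 days; a final interview (Interview 3)
either closes the program (autonomous use) or, when complaints persist
(total > 21), refers the user to a sleep specialist.  Dropout is an
explicit event, legal from every non-terminal stage.

:func:`advance` is a pure function driven by the declarative
:func:`transition_table`, so replaying a recorded event log reproduces the
identical final state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

from .diary import DiaryEntry, derive_night, make_feedback
from .instruments import ISIResult, Occasion, classify_isi

__all__ = [
    "Stage",
    "EventKind",
    "ProtocolEvent",
    "ProtocolState",
    "Action",
    "ProtocolViolation",
    "Transition",
    "advance",
    "transition_table",
    "replay",
    "funnel_counts",
    "FUNNEL_STAGES",
    "state_to_dict",
    "state_from_dict",
    "event_from_dict",
    "STEP1_DIARY_DAYS",
    "STEP2_DAYS",
]

#: diary days required before Interview 2 is requested
STEP1_DIARY_DAYS = 7
#: elapsed days of personalized recommendations before Interview 3
STEP2_DAYS = 10


class Stage(str, Enum):
    REGISTERED = "registered"
    SCREENED_LOW = "screened_low"
    STEP1_DIARY = "step1_diary"
    INTERVIEW2_DUE = "interview2_due"
    STEP2_ACTIVE = "step2_active"
    INTERVIEW3_DUE = "interview3_due"
    AUTONOMOUS_USE = "autonomous_use"
    REFERRED = "referred"
    DROPPED_OUT = "dropped_out"


#: absorbing stages (screened-low users receive hygiene advice and exit)
TERMINAL_STAGES = frozenset(
    {Stage.SCREENED_LOW, Stage.AUTONOMOUS_USE, Stage.REFERRED, Stage.DROPPED_OUT}
)


class EventKind(str, Enum):
    ISI_COMPLETED = "isi_completed"
    DIARY_ENTRY_VALIDATED = "diary_entry_validated"
    STEP2_DAY_ELAPSED = "step2_day_elapsed"
    USER_DROPOUT = "user_dropout"


@dataclass(frozen=True)
class ProtocolEvent:
    kind: EventKind
    payload: Union[ISIResult, DiaryEntry, None] = None

    def __post_init__(self) -> None:
        if self.kind == EventKind.ISI_COMPLETED and not isinstance(
            self.payload, ISIResult
        ):
            raise ValueError("isi_completed event requires an ISIResult payload")
        if self.kind == EventKind.DIARY_ENTRY_VALIDATED and not isinstance(
            self.payload, DiaryEntry
        ):
            raise ValueError("diary_entry_validated event requires a DiaryEntry payload")
        if (
            self.kind in (EventKind.STEP2_DAY_ELAPSED, EventKind.USER_DROPOUT)
            and self.payload is not None
        ):
            raise ValueError(f"{self.kind.value} event carries no payload")


@dataclass(frozen=True)
class ProtocolState:
    """Where one user sits in the program, with ISI history and counters."""

    user_id: str = "user"
    stage: Stage = Stage.REGISTERED
    diary_days_done: int = 0
    step2_days_done: int = 0
    isi_history: Tuple[ISIResult, ...] = ()
    started_at: Optional[datetime] = None


@dataclass(frozen=True)
class Action:
    """An emitted side effect: an advice/template identifier plus params.

    Actions carry template ids (rendered elsewhere), never prose.
    """

    template_id: str
    params: Tuple[Tuple[str, object], ...] = ()

    def param(self, key: str):
        return dict(self.params).get(key)


class ProtocolViolation(RuntimeError):
    """An event that is illegal in the current stage."""


Guard = Callable[[ProtocolState, ProtocolEvent], bool]
ActionFactory = Callable[[ProtocolState, ProtocolEvent], List[Action]]


@dataclass(frozen=True)
class Transition:
    stage: Stage
    event: EventKind
    guard: str  # human-readable guard description
    next_stage: Stage
    actions: str  # human-readable action summary
    _guard_fn: Guard = field(repr=False, compare=False, default=lambda s, e: True)
    _apply: Optional[Callable[[ProtocolState, ProtocolEvent], Tuple[ProtocolState, List[Action]]]] = field(
        repr=False, compare=False, default=None
    )


def _hygiene_actions(state: ProtocolState, event: ProtocolEvent) -> List[Action]:
    return [
        Action("advice.regular_wake_time"),
        Action("advice.morning_light"),
        Action("advice.quiet_dark_room"),
    ]


def _feedback_action(event: ProtocolEvent) -> Action:
    fb = make_feedback(derive_night(event.payload))
    return Action(
        "feedback.morning",
        params=(
            ("tib_hhmm", fb.tib_hhmm),
            ("tst_hhmm", fb.tst_hhmm),
            ("se", fb.se_text),
        ),
    )


def _expected_occasion(state: ProtocolState) -> Occasion:
    return (Occasion.INTERVIEW1, Occasion.INTERVIEW2, Occasion.INTERVIEW3)[
        len(state.isi_history)
    ]


def _check_occasion(state: ProtocolState, event: ProtocolEvent) -> None:
    if len(state.isi_history) >= 3:
        raise ProtocolViolation(
            f"{state.stage.value}: a fourth ISI occasion is not allowed"
        )
    expected = _expected_occasion(state)
    got = event.payload.occasion
    if got is not None and got != expected:
        raise ProtocolViolation(
            f"{state.stage.value}: expected ISI occasion {expected.value}, got {got.value}"
        )


def _build_transitions() -> List[Transition]:
    ts: List[Transition] = []

    def add(stage, event, guard_desc, next_stage, actions_desc, guard_fn, apply_fn):
        ts.append(
            Transition(stage, event, guard_desc, next_stage, actions_desc, guard_fn, apply_fn)
        )

    # --- screening ---------------------------------------------------------
    def screen_low(state, event):
        _check_occasion(state, event)
        new = replace(
            state,
            stage=Stage.SCREENED_LOW,
            isi_history=state.isi_history + (event.payload,),
        )
        return new, _hygiene_actions(state, event)

    add(
        Stage.REGISTERED,
        EventKind.ISI_COMPLETED,
        "total <= 14",
        Stage.SCREENED_LOW,
        "generic hygiene advice bundle",
        lambda s, e: e.payload.total <= 14,
        screen_low,
    )

    def screen_eligible(state, event):
        _check_occasion(state, event)
        new = replace(
            state,
            stage=Stage.STEP1_DIARY,
            isi_history=state.isi_history + (event.payload,),
        )
        return new, [Action("instruction.start_sleep_diary", params=(("days", STEP1_DIARY_DAYS),))]

    add(
        Stage.REGISTERED,
        EventKind.ISI_COMPLETED,
        "total > 14",
        Stage.STEP1_DIARY,
        "sleep-diary instructions (Step 1)",
        lambda s, e: e.payload.total > 14,
        screen_eligible,
    )

    # --- Step 1: diary week ------------------------------------------------
    def diary_progress(state, event):
        days = state.diary_days_done + 1
        actions = [_feedback_action(event)]
        if days >= STEP1_DIARY_DAYS and state.stage == Stage.STEP1_DIARY:
            actions.append(
                Action("interview.request", params=(("occasion", Occasion.INTERVIEW2.value),))
            )
            return replace(state, stage=Stage.INTERVIEW2_DUE, diary_days_done=days), actions
        return replace(state, diary_days_done=days), actions

    add(
        Stage.STEP1_DIARY,
        EventKind.DIARY_ENTRY_VALIDATED,
        "days + 1 < 7",
        Stage.STEP1_DIARY,
        "morning feedback",
        lambda s, e: s.diary_days_done + 1 < STEP1_DIARY_DAYS,
        diary_progress,
    )
    add(
        Stage.STEP1_DIARY,
        EventKind.DIARY_ENTRY_VALIDATED,
        "days + 1 >= 7",
        Stage.INTERVIEW2_DUE,
        "morning feedback + Interview 2 request",
        lambda s, e: s.diary_days_done + 1 >= STEP1_DIARY_DAYS,
        diary_progress,
    )
    # diary entries remain welcome while the interview is pending
    add(
        Stage.INTERVIEW2_DUE,
        EventKind.DIARY_ENTRY_VALIDATED,
        "always",
        Stage.INTERVIEW2_DUE,
        "morning feedback",
        lambda s, e: True,
        diary_progress,
    )

    # --- Interview 2 -> Step 2 ---------------------------------------------
    def interview2(state, event):
        _check_occasion(state, event)
        new = replace(
            state,
            stage=Stage.STEP2_ACTIVE,
            isi_history=state.isi_history + (event.payload,),
        )
        actions = [
            Action("report.week_indicators"),
            Action("instruction.start_recommendations", params=(("days", STEP2_DAYS),)),
        ]
        return new, actions

    add(
        Stage.INTERVIEW2_DUE,
        EventKind.ISI_COMPLETED,
        "occasion is interview2",
        Stage.STEP2_ACTIVE,
        "weekly sleep report + personalized recommendations start",
        lambda s, e: True,
        interview2,
    )

    # --- Step 2: 10 recommendation days ------------------------------------
    def step2_progress(state, event):
        days = state.step2_days_done + 1
        actions = [Action("recommendation.daily")]
        if days >= STEP2_DAYS:
            actions.append(
                Action("interview.request", params=(("occasion", Occasion.INTERVIEW3.value),))
            )
            return replace(state, stage=Stage.INTERVIEW3_DUE, step2_days_done=days), actions
        return replace(state, step2_days_done=days), actions

    add(
        Stage.STEP2_ACTIVE,
        EventKind.STEP2_DAY_ELAPSED,
        "days + 1 < 10",
        Stage.STEP2_ACTIVE,
        "daily recommendation",
        lambda s, e: s.step2_days_done + 1 < STEP2_DAYS,
        step2_progress,
    )
    add(
        Stage.STEP2_ACTIVE,
        EventKind.STEP2_DAY_ELAPSED,
        "days + 1 >= 10",
        Stage.INTERVIEW3_DUE,
        "daily recommendation + Interview 3 request",
        lambda s, e: s.step2_days_done + 1 >= STEP2_DAYS,
        step2_progress,
    )
    add(
        Stage.STEP2_ACTIVE,
        EventKind.DIARY_ENTRY_VALIDATED,
        "always",
        Stage.STEP2_ACTIVE,
        "morning feedback",
        lambda s, e: True,
        diary_progress,
    )

    # --- Interview 3 -> closure or referral --------------------------------
    def interview3(state, event):
        _check_occasion(state, event)
        hist = state.isi_history + (event.payload,)
        if event.payload.total > 21:
            new = replace(state, stage=Stage.REFERRED, isi_history=hist)
            return new, [Action("referral.sleep_specialist")]
        new = replace(state, stage=Stage.AUTONOMOUS_USE, isi_history=hist)
        return new, [Action("closure.autonomous_use")]

    add(
        Stage.INTERVIEW3_DUE,
        EventKind.ISI_COMPLETED,
        "total > 21",
        Stage.REFERRED,
        "referral notice",
        lambda s, e: e.payload.total > 21,
        interview3,
    )
    add(
        Stage.INTERVIEW3_DUE,
        EventKind.ISI_COMPLETED,
        "total <= 21",
        Stage.AUTONOMOUS_USE,
        "closure (autonomous use)",
        lambda s, e: e.payload.total <= 21,
        interview3,
    )

    # --- dropout from every non-terminal stage ------------------------------
    def drop(state, event):
        return replace(state, stage=Stage.DROPPED_OUT), []

    for stage in Stage:
        if stage in TERMINAL_STAGES:
            continue
        add(
            stage,
            EventKind.USER_DROPOUT,
            "always",
            Stage.DROPPED_OUT,
            "dropout record",
            lambda s, e: True,
            drop,
        )

    return ts


_TRANSITIONS = _build_transitions()


def transition_table() -> List[Transition]:
    """The machine-readable transition table that drives :func:`advance`."""
    return list(_TRANSITIONS)


def advance(
    state: ProtocolState, event: ProtocolEvent
) -> Tuple[ProtocolState, List[Action]]:
    """Apply one event; return the new state and the actions it emitted.

    Raises :class:`ProtocolViolation` when the event is illegal in the
    current stage (including any event in a terminal stage).
    """
    if state.stage in TERMINAL_STAGES:
        raise ProtocolViolation(
            f"stage {state.stage.value} is terminal; event {event.kind.value} rejected"
        )
    for t in _TRANSITIONS:
        if t.stage == state.stage and t.event == event.kind and t._guard_fn(state, event):
            return t._apply(state, event)
    raise ProtocolViolation(
        f"event {event.kind.value} is illegal in stage {state.stage.value}"
    )


def replay(
    events: Sequence[ProtocolEvent], initial: Optional[ProtocolState] = None
) -> Tuple[ProtocolState, List[Action]]:
    """Replay an event log from scratch; deterministic and auditable."""
    state = initial if initial is not None else ProtocolState()
    all_actions: List[Action] = []
    for event in events:
        state, actions = advance(state, event)
        all_actions.extend(actions)
    return state, all_actions


# ---------------------------------------------------------------------------
# Adherence funnel
# ---------------------------------------------------------------------------

FUNNEL_STAGES = ("downloaded", "screened", "eligible", "step1_completed", "step2_completed")


def funnel_counts(states: Sequence[ProtocolState]) -> Dict[str, int]:
    """Count users reaching each funnel stage.

    A user counts as *screened* once Interview 1 is answered, *eligible*
    when its total exceeded the clinical threshold, *step1_completed* once
    Interview 2 is answered and *step2_completed* once Interview 3 is
    answered.  Counts are monotone non-increasing along the funnel.
    """
    counts = {k: 0 for k in FUNNEL_STAGES}
    for s in states:
        counts["downloaded"] += 1
        n_isi = len(s.isi_history)
        if n_isi >= 1:
            counts["screened"] += 1
            if s.isi_history[0].eligible_for_intervention:
                counts["eligible"] += 1
                if n_isi >= 2:
                    counts["step1_completed"] += 1
                    if n_isi >= 3:
                        counts["step2_completed"] += 1
    return counts


# ---------------------------------------------------------------------------
# JSON session serialization
# ---------------------------------------------------------------------------


def _isi_to_dict(r: ISIResult) -> dict:
    return {
        "total": r.total,
        "band": r.band.value,
        "occasion": r.occasion.value if r.occasion else None,
    }


def state_to_dict(state: ProtocolState) -> dict:
    return {
        "user_id": state.user_id,
        "stage": state.stage.value,
        "diary_days_done": state.diary_days_done,
        "step2_days_done": state.step2_days_done,
        "isi_history": [_isi_to_dict(r) for r in state.isi_history],
        "started_at": state.started_at.isoformat() if state.started_at else None,
    }


def state_from_dict(doc: dict) -> ProtocolState:
    hist = tuple(
        classify_isi(
            r["total"],
            occasion=Occasion(r["occasion"]) if r.get("occasion") else None,
        )
        for r in doc.get("isi_history", [])
    )
    started = doc.get("started_at")
    return ProtocolState(
        user_id=doc.get("user_id", "user"),
        stage=Stage(doc["stage"]),
        diary_days_done=int(doc.get("diary_days_done", 0)),
        step2_days_done=int(doc.get("step2_days_done", 0)),
        isi_history=hist,
        started_at=datetime.fromisoformat(started) if started else None,
    )


def event_from_dict(doc: dict) -> ProtocolEvent:
    """Build an event from JSON, e.g. {"kind": "isi_completed", "total": 16,
    "occasion": "interview1"} or a diary-entry payload under "entry"."""
    kind = EventKind(doc["kind"])
    if kind == EventKind.ISI_COMPLETED:
        occ = Occasion(doc["occasion"]) if doc.get("occasion") else None
        return ProtocolEvent(kind, classify_isi(int(doc["total"]), occasion=occ))
    if kind == EventKind.DIARY_ENTRY_VALIDATED:
        from .diary import parse_diary_row

        return ProtocolEvent(kind, parse_diary_row(doc["entry"]))
    return ProtocolEvent(kind)
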