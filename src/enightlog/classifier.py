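"""Decision-tree state machine over frame features, with two-level alarms.

Six states describe the monitored bed: ``sleep_locked`` (monitoring armed,
subject lying below the sleep level), ``sit`` (torso raised above the sleep
level), ``exiting_bed`` (subject in the leave zone), ``leave`` (subject has
crossed the boundary and left the monitored zones), ``others`` (a
non-monitored person — caregiver or visitor — inside the zones while the
subject stays on the bed), and ``both_leave`` (visitor and subject both gone).

Alarms follow the zone semantics: activity between bed and leave zone raises
only the first-level *yellow* alarm (sitting on the edge, standing by the
bed); crossing the boundary zone raises the second-level *red* alarm.
Caregiver presence is recognised but never alarmed.

The radar's breaths-per-minute signal is used strictly as a presence check —
a valid rate (or a motion-corrupted sample) means somebody is on the bed — and
never as a posture feature.

The published description of this classifier names the states, thresholds and
alarm levels but not the branch order, so the transition table below is an
explicit reconstruction: ordered tests per frame, first match wins, and a
state change must persist for ``debounce_frames`` consecutive frames before it
commits.  Event extraction emits one bed-exit per transition into ``leave`` or
``both_leave`` once the classifier has armed (subject lying with a valid rate
for two seconds); returning to bed re-arms detection, so the toilet scenario
yields two events.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable

from .geometry import FPS, FRAME_HEIGHT, FRAME_WIDTH
from .pipeline import FrameFeatures


class State(str, enum.Enum):
    SLEEP_LOCKED = "sleep_locked"
    SIT = "sit"
    EXITING_BED = "exiting_bed"
    LEAVE = "leave"
    OTHERS = "others"
    BOTH_LEAVE = "both_leave"


class Alarm(str, enum.Enum):
    NONE = "none"
    YELLOW = "yellow"
    RED = "red"


#: states that emit a bed-exit event when entered
EXIT_STATES = (State.LEAVE, State.BOTH_LEAVE)
#: frames of lying-with-valid-rate required before monitoring arms (2 s)
ARMING_FRAMES = 2 * FPS


@dataclass(frozen=True)
class ThresholdSet:
    """Pixel-count thresholds of the decision tree (all in pixels)."""

    pth_above_sleep_level: int = 800
    pth_leave_zone: int = 200
    pth_boundary: int = 200
    pth_motion: int = 50
    debounce_frames: int = 3

    def __post_init__(self) -> None:
        n_px = FRAME_WIDTH * FRAME_HEIGHT
        for name in ("pth_above_sleep_level", "pth_leave_zone", "pth_boundary",
                     "pth_motion"):
            v = getattr(self, name)
            if not (0 < v < n_px):
                raise ValueError(f"{name}={v} outside (0, {n_px})")
        if self.debounce_frames < 1:
            raise ValueError("debounce_frames must be >= 1")


@dataclass(frozen=True)
class ClassifierState:
    """Current/previous committed state, alarm, and debounce bookkeeping."""

    state: State = State.LEAVE  # nobody present before the subject arrives
    prev_state: State = State.LEAVE
    alarm: Alarm = Alarm.NONE
    entered_at_s: float = 0.0
    armed: bool = False
    pending: State | None = None
    pending_count: int = 0
    lying_streak: int = 0

    @staticmethod
    def initial() -> "ClassifierState":
        return ClassifierState()


def alarm_for(state: State) -> Alarm:
    """Alarm level of a state: bedside activity yellow, boundary crossing red."""
    if state in (State.SIT, State.EXITING_BED):
        return Alarm.YELLOW
    if state in (State.LEAVE, State.BOTH_LEAVE):
        return Alarm.RED
    return Alarm.NONE  # sleep_locked and caregiver presence are not alarmed


def _signals(f: FrameFeatures, th: ThresholdSet):
    presence = f.b_bpm > 0 or f.b_motion
    raised = f.p_bed_zone > th.pth_above_sleep_level
    in_leave = f.p_leave_zone > th.pth_leave_zone
    in_boundary = f.p_boundary_zone > th.pth_boundary
    return presence, raised, in_leave, in_boundary


def track_visitor(
    features: FrameFeatures, prev: State, thresholds: ThresholdSet
) -> State | None:
    """Visitor disambiguation: zone activity while the subject stays on bed.

    Activity arriving in the leave/boundary rings while the radar still
    confirms the subject on the bed is a non-monitored person (``others``).
    From ``others``, all presence vanishing means ``both_leave``; the zones
    emptying with the subject still present falls back to ``sleep_locked``.
    Returns None when no visitor rule applies.
    """
    presence, raised, in_leave, in_boundary = _signals(features, thresholds)
    if prev == State.SLEEP_LOCKED and not raised and (in_leave or in_boundary):
        return State.OTHERS if presence else None
    if prev == State.OTHERS:
        if raised:
            return State.SIT
        if in_leave or in_boundary:
            return State.OTHERS
        return State.SLEEP_LOCKED if presence else State.BOTH_LEAVE
    return None


def _candidate(f: FrameFeatures, prev: State, th: ThresholdSet) -> State:
    """Next-state candidate: ordered tests per frame, first match wins."""
    presence, raised, in_leave, in_boundary = _signals(f, th)
    empty = not (raised or in_leave or in_boundary)

    if prev == State.SLEEP_LOCKED:
        if raised:
            return State.SIT
        visitor = track_visitor(f, prev, th)
        if visitor is not None:
            return visitor
        if in_leave or in_boundary:  # activity without radar presence
            return State.EXITING_BED
        return State.SLEEP_LOCKED

    if prev == State.SIT:
        if in_leave:
            return State.EXITING_BED
        if raised:
            return State.SIT
        if in_boundary:
            return State.OTHERS if presence else State.EXITING_BED
        if presence:
            return State.SLEEP_LOCKED  # lay back down below the sleep level
        return State.SIT

    if prev == State.EXITING_BED:
        if empty and not presence:
            return State.LEAVE  # crossed the boundary and gone
        if raised:
            return State.SIT
        if in_leave or in_boundary:
            return State.EXITING_BED
        return State.SLEEP_LOCKED  # zones empty but subject back on the bed

    if prev == State.OTHERS:
        visitor = track_visitor(f, prev, th)
        assert visitor is not None
        return visitor

    # prev in (LEAVE, BOTH_LEAVE): watch for re-entry
    if raised:
        return State.SIT
    if in_leave or in_boundary:
        return State.EXITING_BED
    if presence:
        return State.SLEEP_LOCKED
    return prev


def classify(
    features: FrameFeatures,
    prev: ClassifierState,
    thresholds: ThresholdSet,
) -> ClassifierState:
    """Advance the state machine by one frame.

    A differing candidate state must persist ``debounce_frames`` consecutive
    frames before committing, so single-frame feature spikes never change the
    state.  Monitoring arms once the subject has been lying with a valid radar
    rate for two seconds; events are only meaningful once armed.
    """
    cand = _candidate(features, prev.state, thresholds)

    if cand == prev.state:
        pending, count = None, 0
        state = prev.state
    elif cand == prev.pending:
        count = prev.pending_count + 1
        if count >= thresholds.debounce_frames:
            state, pending, count = cand, None, 0
        else:
            state, pending = prev.state, cand
    else:
        state, pending, count = prev.state, cand, 1
        if thresholds.debounce_frames == 1:
            state, pending, count = cand, None, 0

    changed = state != prev.state
    presence = features.b_bpm > 0 or features.b_motion
    lying = state == State.SLEEP_LOCKED and presence
    streak = prev.lying_streak + 1 if lying else 0
    armed = prev.armed or streak >= ARMING_FRAMES
    return ClassifierState(
        state=state,
        prev_state=prev.state if changed else prev.prev_state,
        # no alarms before monitoring arms (states are still reported)
        alarm=alarm_for(state) if armed else Alarm.NONE,
        entered_at_s=features.timestamp_s if changed else prev.entered_at_s,
        armed=armed,
        pending=pending,
        pending_count=count,
        lying_streak=streak,
    )


@dataclass(frozen=True)
class StateRecord:
    timestamp_s: float
    state: State
    alarm: Alarm
    armed: bool


def run_classifier(
    features: Iterable[FrameFeatures],
    thresholds: ThresholdSet | None = None,
    initial: ClassifierState | None = None,
) -> list[StateRecord]:
    """Run the state machine over a feature stream, returning the state log."""
    th = thresholds or ThresholdSet()
    cs = initial or ClassifierState.initial()
    log: list[StateRecord] = []
    for f in features:
        cs = classify(f, cs, th)
        log.append(StateRecord(f.timestamp_s, cs.state, cs.alarm, cs.armed))
    return log


def extract_exit_events(state_log: Iterable[StateRecord]) -> list[float]:
    """Timestamps of bed-exit events: armed transitions into leave/both_leave.

    Leaving the exit states re-arms detection, so a trial with two separate
    leave episodes yields two events.
    """
    events: list[float] = []
    prev: State | None = None
    for rec in state_log:
        if rec.state in EXIT_STATES and prev not in EXIT_STATES and prev is not None:
            if rec.armed:
                events.append(float(rec.timestamp_s))
        prev = rec.state
    return events
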