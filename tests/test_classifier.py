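"""State machine transitions, alarms, debounce, visitor logic, events."""

import numpy as np
import pytest

import enightlog as en
from enightlog.classifier import (
    ARMING_FRAMES,
    Alarm,
    ClassifierState,
    State,
    StateRecord,
    ThresholdSet,
    alarm_for,
    classify,
    extract_exit_events,
    run_classifier,
    track_visitor,
)
from enightlog.pipeline import FrameFeatures

TH1 = ThresholdSet(debounce_frames=1)  # immediate commits for table walks


def feats(t=0.0, bed=0, leave=0, boundary=0, bpm=0.0, motion=False):
    return FrameFeatures(timestamp_s=t, p_bed_zone=bed, p_leave_zone=leave,
                         p_boundary_zone=boundary, b_bpm=bpm, b_motion=motion)


def state(s, armed=True):
    return ClassifierState(state=s, prev_state=s, armed=armed)


def step(f, s, th=TH1):
    return classify(f, state(s), th).state


# -- decision table ------------------------------------------------------------


def test_quiet_sleep_stays_locked():
    assert step(feats(bpm=14.0), State.SLEEP_LOCKED) == State.SLEEP_LOCKED


def test_raised_torso_means_sitting():
    f = feats(bed=TH1.pth_above_sleep_level + 1, bpm=14.0)
    assert step(f, State.SLEEP_LOCKED) == State.SIT


def test_sit_to_leave_zone_means_exiting():
    f = feats(leave=TH1.pth_leave_zone + 1, motion=True)
    assert step(f, State.SIT) == State.EXITING_BED


def test_exit_completes_when_zones_empty_and_no_presence():
    # boundary crossing keeps the exiting state ...
    f1 = feats(boundary=TH1.pth_boundary + 1)
    assert step(f1, State.EXITING_BED) == State.EXITING_BED
    # ... then everything empties with no radar presence: subject left
    f2 = feats()
    assert step(f2, State.EXITING_BED) == State.LEAVE


def test_lying_back_down_returns_to_sleep():
    assert step(feats(bpm=13.0), State.SIT) == State.SLEEP_LOCKED
    assert step(feats(bpm=13.0), State.EXITING_BED) == State.SLEEP_LOCKED


def test_reentry_from_leave():
    f = feats(boundary=TH1.pth_boundary + 1)
    assert step(f, State.LEAVE) == State.EXITING_BED


# -- visitor logic -------------------------------------------------------------


def test_visitor_while_subject_lying_is_others():
    f = feats(leave=TH1.pth_leave_zone + 1, bpm=14.0)
    assert track_visitor(f, State.SLEEP_LOCKED, TH1) == State.OTHERS
    assert step(f, State.SLEEP_LOCKED) == State.OTHERS


def test_others_then_all_gone_is_both_leave():
    f = feats()  # zones empty, no radar presence
    assert track_visitor(f, State.OTHERS, TH1) == State.BOTH_LEAVE
    assert step(f, State.OTHERS) == State.BOTH_LEAVE


def test_visitor_departs_subject_still_lying():
    f = feats(bpm=14.0)
    assert step(f, State.OTHERS) == State.SLEEP_LOCKED


def test_caregiver_presence_never_alarms():
    assert alarm_for(State.OTHERS) == Alarm.NONE


def test_visitor_visit_replay_leaves_no_events():
    """A visitor entering and leaving while the subject sleeps: no bed exit."""
    th = ThresholdSet(debounce_frames=2)
    seq = (
        [feats(t=i / 6, bpm=14.0) for i in range(30)]
        + [feats(t=(30 + i) / 6, boundary=300, bpm=14.0) for i in range(6)]
        + [feats(t=(36 + i) / 6, leave=300, bpm=14.0) for i in range(30)]
        + [feats(t=(66 + i) / 6, boundary=300, bpm=14.0) for i in range(6)]
        + [feats(t=(72 + i) / 6, bpm=14.0) for i in range(30)]
    )
    log = run_classifier(seq, th)
    assert extract_exit_events(log) == []
    states = {r.state for r in log}
    assert State.OTHERS in states
    assert log[-1].state == State.SLEEP_LOCKED
    assert all(r.alarm != Alarm.RED for r in log)


# -- alarms --------------------------------------------------------------------


@pytest.mark.parametrize("s,a", [
    (State.SLEEP_LOCKED, Alarm.NONE),
    (State.SIT, Alarm.YELLOW),
    (State.EXITING_BED, Alarm.YELLOW),
    (State.LEAVE, Alarm.RED),
    (State.BOTH_LEAVE, Alarm.RED),
    (State.OTHERS, Alarm.NONE),
])
def test_alarm_levels(s, a):
    assert alarm_for(s) == a


def test_exit_trajectory_alarm_ordering():
    """Lying -> sit -> stand -> cross boundary: none, yellow, then red."""
    th = ThresholdSet(debounce_frames=2)
    seq = (
        [feats(t=i / 6, bpm=14.0) for i in range(ARMING_FRAMES + 6)]
        + [feats(t=3 + i / 6, bed=1200, bpm=14.0) for i in range(12)]
        + [feats(t=5 + i / 6, leave=800, motion=True) for i in range(12)]
        + [feats(t=7 + i / 6, boundary=800) for i in range(6)]
        + [feats(t=8 + i / 6) for i in range(12)]
    )
    log = run_classifier(seq, th)
    compressed = []
    for r in log:
        if not compressed or compressed[-1] != r.alarm:
            compressed.append(r.alarm)
    assert compressed == [Alarm.NONE, Alarm.YELLOW, Alarm.RED]
    assert len(extract_exit_events(log)) == 1


# -- debounce ------------------------------------------------------------------


@pytest.mark.parametrize("debounce", [2, 3, 5])
def test_single_frame_spike_never_changes_state(debounce):
    th = ThresholdSet(debounce_frames=debounce)
    cs = state(State.SLEEP_LOCKED)
    quiet = feats(bpm=14.0)
    spike = feats(leave=5000, boundary=5000, bpm=14.0)
    cs = classify(quiet, cs, th)
    cs = classify(spike, cs, th)  # one-frame burst
    assert cs.state == State.SLEEP_LOCKED
    cs = classify(quiet, cs, th)
    assert cs.state == State.SLEEP_LOCKED and cs.pending is None


def test_persistent_condition_commits_after_debounce():
    th = ThresholdSet(debounce_frames=3)
    cs = state(State.SLEEP_LOCKED)
    f = feats(bed=2000, bpm=14.0)
    for i in range(2):
        cs = classify(f, cs, th)
        assert cs.state == State.SLEEP_LOCKED
    cs = classify(f, cs, th)
    assert cs.state == State.SIT


# -- arming and events ---------------------------------------------------------


def test_no_events_before_arming():
    th = ThresholdSet(debounce_frames=1)
    # an unattended burst of zone activity before anyone ever lay down
    seq = ([feats(t=i / 6) for i in range(6)]
           + [feats(t=1 + i / 6, leave=900) for i in range(6)]
           + [feats(t=2 + i / 6) for i in range(6)])
    log = run_classifier(seq, th)
    assert extract_exit_events(log) == []
    assert not log[-1].armed


def test_two_leave_episodes_two_events():
    th = ThresholdSet(debounce_frames=1)
    lying = [feats(t=0, bpm=14.0)] * (ARMING_FRAMES + 2)
    exit_ = [feats(t=1, leave=900)] * 3 + [feats(t=2)] * 6
    back = [feats(t=3, boundary=900)] * 3 + [feats(t=4, bpm=14.0)] * (ARMING_FRAMES + 2)
    log = run_classifier(lying + exit_ + back + exit_, th)
    assert len(extract_exit_events(log)) == 2


def test_sequence_without_leave_has_no_events():
    th = ThresholdSet(debounce_frames=1)
    seq = ([feats(t=i / 6, bpm=14.0) for i in range(ARMING_FRAMES + 2)]
           + [feats(t=3 + i / 6, bed=2000, bpm=14.0) for i in range(6)]
           + [feats(t=4 + i / 6, bpm=14.0) for i in range(6)])
    assert extract_exit_events(run_classifier(seq, th)) == []


def test_threshold_validation():
    with pytest.raises(ValueError):
        ThresholdSet(pth_leave_zone=0)
    with pytest.raises(ValueError):
        ThresholdSet(pth_above_sleep_level=512 * 424)
    with pytest.raises(ValueError):
        ThresholdSet(debounce_frames=0)
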