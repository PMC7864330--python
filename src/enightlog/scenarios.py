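"""Scripted bed-time scenarios.

Nine scenarios (Sc1–Sc9) cover the typical night-time episodes a hostel
caregiver sees: a plain exit, rolling over, a toilet trip (two exits),
drinking, using a remote control, sneezing, a caregiver assisting and
checking, a visitor checking, and coughing.  Each scenario is an ordered list
of scripted steps performed by a subject and, in two scenarios, a caregiver
or visitor.  Every scenario ends with the subject leaving the bed; the toilet
scenario (Sc3) contains the full sequence twice and therefore two bed-exit
moves, all others exactly one.

For the double-bed room three scenarios (Sc3, Sc7, Sc8) have modified
variants: the toilet trip routes through the other bed's monitored zone, and
the caregiver/visitor checks on both subjects before returning to the door.
"""

from __future__ import annotations

from dataclasses import dataclass

SCENARIO_IDS = tuple(f"Sc{i}" for i in range(1, 10))

#: scenarios with a dedicated double-bed variant; the rest reuse the single script
DOUBLE_VARIANTS = ("Sc3", "Sc7", "Sc8")

# -- canonical actions -------------------------------------------------------
# subject actions
WALK_IN = "walk_in"
WALK_IN_ASSISTED = "walk_in_assisted"
SIT_EDGE = "sit_edge"
MOVE_CENTRE = "move_centre"
LIE = "lie"
COVER_QUILT = "cover_quilt"
SLEEP = "sleep"
WAKE = "wake"
ROLL = "roll"
FLIP_QUILT = "flip_quilt"
SIT_UP = "sit_up"
MOVE_EDGE = "move_edge"
STAND_UP = "stand_up"
LEAVE_BED = "leave_bed"
LEAVE_BED_VIA_OTHER_ZONE = "leave_bed_via_other_zone"
DRINK = "drink"
USE_DEVICE = "use_device"
SNEEZE = "sneeze"
BREATHE_DIFFICULTY = "breathe_difficulty"
ITCHY_THROAT = "itchy_throat"
COUGH = "cough"
# caregiver / visitor actions
CAREGIVER_CHECK = "caregiver_check"
CAREGIVER_CHECK_BOTH = "caregiver_check_both"
CAREGIVER_LEAVE = "caregiver_leave"
VISITOR_CHECK = "visitor_check"
VISITOR_CHECK_BOTH = "visitor_check_both"
VISITOR_LEAVE = "visitor_leave"

LEAVE_ACTIONS = (LEAVE_BED, LEAVE_BED_VIA_OTHER_ZONE)

#: default duration (s) of each action; the simulator adds seeded jitter
DEFAULT_DURATIONS_S: dict[str, float] = {
    WALK_IN: 5.0,
    WALK_IN_ASSISTED: 6.0,
    SIT_EDGE: 3.0,
    MOVE_CENTRE: 3.0,
    LIE: 2.0,
    COVER_QUILT: 3.0,
    SLEEP: 6.0,
    WAKE: 2.0,
    ROLL: 4.0,
    FLIP_QUILT: 2.0,
    SIT_UP: 3.0,
    MOVE_EDGE: 3.0,
    STAND_UP: 2.0,
    LEAVE_BED: 5.0,
    LEAVE_BED_VIA_OTHER_ZONE: 10.0,
    DRINK: 4.0,
    USE_DEVICE: 4.0,
    SNEEZE: 3.0,
    BREATHE_DIFFICULTY: 3.0,
    ITCHY_THROAT: 2.0,
    COUGH: 3.0,
    CAREGIVER_CHECK: 6.0,
    CAREGIVER_CHECK_BOTH: 12.0,
    CAREGIVER_LEAVE: 4.0,
    VISITOR_CHECK: 7.0,
    VISITOR_CHECK_BOTH: 12.0,
    VISITOR_LEAVE: 4.0,
}


@dataclass(frozen=True)
class Step:
    """One scripted step: the protocol label, its canonical action, and actor."""

    index: int
    label: str
    action: str
    actor: str  # 'subject' | 'caregiver' | 'visitor'


@dataclass(frozen=True)
class ScenarioScript:
    """A compiled scenario: ordered steps plus ground-truth bookkeeping.

    ``move_starts`` holds the step index at which each scenario move begins
    (Sc3 has two moves — the script repeats — all others one).
    """

    scenario_id: str
    setting: str
    steps: tuple[Step, ...]
    expected_exits: int
    move_starts: tuple[int, ...]

    def __post_init__(self) -> None:
        exits = [s for s in self.steps if s.action in LEAVE_ACTIONS]
        if len(exits) != self.expected_exits:
            raise ValueError("leave-bed step count disagrees with expected exits")
        if self.steps[-1].action not in LEAVE_ACTIONS or self.steps[-1].actor != "subject":
            raise ValueError("every script must end with the subject leaving the bed")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


# The nine step columns of the single-bed protocol, by scenario.
_STEP_TABLE: dict[str, list[str]] = {
    "Sc1": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Wake up", "Flip over quilt", "Sit on bed", "Move to edge",
        "Stand up", "Leave bed",
    ],
    "Sc2": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Roll over", "Wake up", "Flip over quilt", "Sit on bed",
        "Move to edge", "Stand up", "Leave bed",
    ],
    # Sc3 = Sc2's thirteen steps performed twice (toilet trip and return)
    "Sc4": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Roll over", "Wake up", "Flip over quilt", "Sit on bed",
        "Drink water", "Sleep", "Roll over", "Wake up", "Sit on bed",
        "Move to edge", "Stand up", "Leave bed",
    ],
    "Sc5": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Roll over", "Wake up", "Flip over quilt", "Sit/lay on bed",
        "Use of device", "Sleep", "Roll over", "Wake up", "Sit on bed",
        "Move to edge", "Stand up", "Leave bed",
    ],
    "Sc6": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Roll over", "Difficult breathing", "Wake up", "Sit on bed",
        "Sneeze/cough", "Sleep", "Roll over", "Wake up", "Sit on bed",
        "Move to edge", "Stand up", "Leave bed",
    ],
    "Sc7": [
        "Walk in with caregiver", "Sit on bed", "Move to centre", "Lying",
        "Cover with quilt", "Caregiver check", "Caregiver leave", "Sleep",
        "Visitor walk in check", "Visitor leave", "Sleep", "Wake up",
        "Flip over quilt", "Sit on bed", "Move to edge", "Stand up", "Leave bed",
    ],
    "Sc8": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Visitor walk in check", "Visitor leave", "Sleep", "Wake up",
        "Flip over quilt", "Sit on bed", "Move to edge", "Stand up", "Leave bed",
    ],
    "Sc9": [
        "Walk in", "Sit on bed", "Move to centre", "Lying", "Cover with quilt",
        "Sleep", "Roll over", "Itchy throat", "Wake up", "Cough",
        "Drink water", "Sleep", "Roll over", "Wake up", "Sit on bed",
        "Move to edge", "Stand up", "Leave bed",
    ],
}
_STEP_TABLE["Sc3"] = list(_STEP_TABLE["Sc2"])  # performed twice, see compile

_LABEL_ACTIONS: dict[str, tuple[str, str]] = {
    "Walk in": (WALK_IN, "subject"),
    "Walk in with caregiver": (WALK_IN_ASSISTED, "subject"),
    "Move to centre": (MOVE_CENTRE, "subject"),
    "Lying": (LIE, "subject"),
    "Cover with quilt": (COVER_QUILT, "subject"),
    "Sleep": (SLEEP, "subject"),
    "Wake up": (WAKE, "subject"),
    "Roll over": (ROLL, "subject"),
    "Flip over quilt": (FLIP_QUILT, "subject"),
    "Move to edge": (MOVE_EDGE, "subject"),
    "Stand up": (STAND_UP, "subject"),
    "Leave bed": (LEAVE_BED, "subject"),
    "Drink water": (DRINK, "subject"),
    "Use of device": (USE_DEVICE, "subject"),
    "Sit/lay on bed": (SIT_UP, "subject"),
    "Sneeze/cough": (SNEEZE, "subject"),
    "Difficult breathing": (BREATHE_DIFFICULTY, "subject"),
    "Itchy throat": (ITCHY_THROAT, "subject"),
    "Cough": (COUGH, "subject"),
    "Caregiver check": (CAREGIVER_CHECK, "caregiver"),
    "Caregiver leave": (CAREGIVER_LEAVE, "caregiver"),
    "Visitor walk in check": (VISITOR_CHECK, "visitor"),
    "Visitor leave": (VISITOR_LEAVE, "visitor"),
}


def _action_for(label: str, prev_action: str | None) -> tuple[str, str]:
    if label == "Sit on bed":
        # after entering the room the subject sits on the bed edge; after
        # waking mid-scenario they sit up where they lie
        if prev_action in (WALK_IN, WALK_IN_ASSISTED):
            return SIT_EDGE, "subject"
        return SIT_UP, "subject"
    return _LABEL_ACTIONS[label]


def compile_scenario(scenario_id: str, setting: str = "single") -> ScenarioScript:
    """Compile one scenario into an ordered step script.

    ``setting`` selects the single- or double-bed variant; only Sc3, Sc7 and
    Sc8 have a double variant (toilet trip through the other monitored zone,
    caregiver/visitor checking both beds), all other scenarios reuse the
    single-bed script.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id {scenario_id!r}")
    if setting not in ("single", "double"):
        raise ValueError(f"unknown setting {setting!r}")
    labels = list(_STEP_TABLE[scenario_id])
    move_starts = [0]
    if scenario_id == "Sc3":
        move_starts.append(len(labels))
        labels = labels + labels  # "Repeat step 1 to 13"

    double = setting == "double" and scenario_id in DOUBLE_VARIANTS
    steps: list[Step] = []
    prev_action: str | None = None
    for i, label in enumerate(labels):
        action, actor = _action_for(label, prev_action)
        if double:
            if action == LEAVE_BED and scenario_id == "Sc3" and i < len(labels) - 1:
                # the toilet trip passes through the other bed's zones
                action = LEAVE_BED_VIA_OTHER_ZONE
            elif action == CAREGIVER_CHECK:
                action = CAREGIVER_CHECK_BOTH
            elif action == VISITOR_CHECK:
                action = VISITOR_CHECK_BOTH
        steps.append(Step(index=i, label=label, action=action, actor=actor))
        prev_action = action

    return ScenarioScript(
        scenario_id=scenario_id,
        setting=setting if double else "single",
        steps=tuple(steps),
        expected_exits=2 if scenario_id == "Sc3" else 1,
        move_starts=tuple(move_starts),
    )
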