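"""Conventional bed-exit detection (CBD): pressure mat + infrared fence.

The comparator system is a pressure mat on the bed surface and a
retro-reflective infrared fence along the bed's exit side.  Both show an
on-status while the subject sits on the bed side; an exit is recognised from
the ordered signal sequence

    (mat on AND beam on)  ->  mat off (subject stood up)  ->  beam off
                                                     (subject left the zone),

completed within a pattern window.  The beam is modelled as presence
detection — on whenever a body stands in the beam path — which matches the
described on/off semantics; visitors walking through the fence therefore
pulse it, the mechanism behind the baseline's false alarms in rooms with
more than one bed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BedGeometry, Rect, RoomLayout
from .simulator import ActorState, LYING, ROLLING, SITTING, STANDING

#: default window (s) within which the three-phase pattern must complete
DEFAULT_PATTERN_WINDOW_S = 30.0
#: mat length along the bed axis (cm); the mat lies flush with the exit edge
MAT_LENGTH_CM = 120.0
MAT_DEPTH_CM = 60.0
#: beam offset outside the exit face and its modelled thickness (cm)
BEAM_OFFSET_CM = 20.0
BEAM_THICKNESS_CM = 6.0
#: how close (cm) a standing visitor must be for a lean to press the mat
LEAN_REACH_CM = 15.0


@dataclass
class SensorTrace:
    """Per-frame mat and beam status (True = on) with timestamps."""

    times_s: np.ndarray
    mat_on: np.ndarray
    beam_on: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times_s) == len(self.mat_on) == len(self.beam_on)):
            raise ValueError("mat and beam series must align with the timestamps")

    def __len__(self) -> int:
        return len(self.times_s)


def mat_rect(bed: BedGeometry) -> Rect:
    """Pressure-mat rectangle: flush with the exit edge, centred along the bed."""
    cx, cy = bed.rect.centre
    s = bed.exit_side
    if s in ("x0", "x1"):
        y0, y1 = cy - MAT_LENGTH_CM / 2, cy + MAT_LENGTH_CM / 2
        if s == "x0":
            return Rect(bed.rect.x0, y0, bed.rect.x0 + MAT_DEPTH_CM, y1)
        return Rect(bed.rect.x1 - MAT_DEPTH_CM, y0, bed.rect.x1, y1)
    x0, x1 = cx - MAT_LENGTH_CM / 2, cx + MAT_LENGTH_CM / 2
    if s == "y0":
        return Rect(x0, bed.rect.y0, x1, bed.rect.y0 + MAT_DEPTH_CM)
    return Rect(x0, bed.rect.y1 - MAT_DEPTH_CM, x1, bed.rect.y1)


def beam_rect(bed: BedGeometry) -> Rect:
    """Infrared-fence line, ``BEAM_OFFSET_CM`` outside the exit face."""
    s = bed.exit_side
    if s in ("x0", "x1"):
        x = bed.rect.x0 - BEAM_OFFSET_CM if s == "x0" else bed.rect.x1 + BEAM_OFFSET_CM
        return Rect(x - BEAM_THICKNESS_CM / 2, bed.rect.y0,
                    x + BEAM_THICKNESS_CM / 2, bed.rect.y1)
    y = bed.rect.y0 - BEAM_OFFSET_CM if s == "y0" else bed.rect.y1 + BEAM_OFFSET_CM
    return Rect(bed.rect.x0, y - BEAM_THICKNESS_CM / 2,
                bed.rect.x1, y + BEAM_THICKNESS_CM / 2)


def simulate_pressure_mat(
    actor_frames: list[dict[str, ActorState]],
    mat: Rect,
    bed: BedGeometry,
    fps: int = 6,
    visitor_presses_mat: bool = True,
) -> np.ndarray:
    """Per-frame mat status: on while a body's weight rests on the mat.

    A lying or sitting body whose footprint overlaps the mat presses it;
    partial overlap counts (sitting on the bed side).  With
    ``visitor_presses_mat`` a standing person leaning over the bed edge
    (within ``LEAN_REACH_CM`` of the mat) also presses it — the mechanism that
    lets caregiver checks disturb the mat signal.
    """
    if not bed.rect.contains_rect(mat):
        raise ValueError("mat rectangle must lie within the bed rectangle")
    on = np.zeros(len(actor_frames), dtype=bool)
    for i, states in enumerate(actor_frames):
        for a in states.values():
            fp = a.footprint()
            if fp is None:
                continue
            if a.posture in (LYING, ROLLING, SITTING) and fp.intersects(mat):
                on[i] = True
                break
            if (visitor_presses_mat and a.posture == STANDING and not a.moving
                    and fp.dilate(LEAN_REACH_CM).intersects(mat)):
                on[i] = True
                break
    return on


def simulate_ir_fence(
    actor_frames: list[dict[str, ActorState]],
    beam: Rect,
    fps: int = 6,
) -> np.ndarray:
    """Per-frame beam status: on while any body stands in the beam path."""
    on = np.zeros(len(actor_frames), dtype=bool)
    for i, states in enumerate(actor_frames):
        for a in states.values():
            fp = a.footprint()
            if fp is not None and fp.intersects(beam):
                on[i] = True
                break
    return on


def simulate_cbd_trace(
    actor_frames: list[dict[str, ActorState]],
    layout: RoomLayout,
    bed_index: int = 0,
    fps: int = 6,
    visitor_presses_mat: bool = True,
) -> SensorTrace:
    """Convenience: mat + beam traces for one bed of a simulated trial."""
    bed = layout.beds[bed_index]
    return SensorTrace(
        times_s=np.arange(len(actor_frames)) / fps,
        mat_on=simulate_pressure_mat(
            actor_frames, mat_rect(bed), bed, fps=fps,
            visitor_presses_mat=visitor_presses_mat,
        ),
        beam_on=simulate_ir_fence(actor_frames, beam_rect(bed), fps=fps),
    )


def cbd_detect(
    trace: SensorTrace,
    pattern_window_s: float = DEFAULT_PATTERN_WINDOW_S,
) -> list[float]:
    """Detect bed exits from the mat/beam signal sequence.

    Emits one event per completed pattern — (mat on AND beam on), then mat
    off, then beam off — with each phase reached within ``pattern_window_s``
    of the pattern's start; partial or timed-out patterns emit nothing.
    The event carries the timestamp of the final (beam off) transition.
    """
    events: list[float] = []
    phase = 0  # 0: seek mat&beam on, 1: seek mat off, 2: seek beam off
    armed_at = 0.0
    for t, mat, beam in zip(trace.times_s, trace.mat_on, trace.beam_on):
        if phase >= 1 and t - armed_at > pattern_window_s:
            phase = 0
        if phase == 0:
            if mat and beam:
                phase, armed_at = 1, float(t)
        elif phase == 1:
            if mat and beam:
                armed_at = float(t)  # still sitting on the edge: refresh window
            if not mat:
                phase = 2
                if not beam:  # mat and beam dropped within the same frame
                    events.append(float(t))
                    phase = 0
        elif phase == 2:
            if mat and beam:
                # subject sat back down: restart the armed pattern
                phase, armed_at = 1, float(t)
            elif not beam:
                events.append(float(t))
                phase = 0
    return events
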