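"""Synthetic depth-scene simulator.

Generates what the ceiling-mounted time-of-flight sensor and the bedside
ultrawideband radar would record while actors perform the scripted bed-time
scenarios: per-frame actor states at 6 frames/s, 512x424 depth frames with
optional Gaussian sensor noise, a per-second breaths-per-minute series, and a
ground-truth log of bed-exit events.

Actors are modelled as axis-aligned cuboids (torso footprint x top height per
posture): only zone pixel counts matter downstream, so an articulated body
model would add nothing.  Rendering is orthographic — each pixel takes the
depth of the tallest surface under it (nearest surface wins), clamped to
[0, D_floor].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    FPS,
    BedGeometry,
    Rect,
    RoomLayout,
    SensorView,
    ZoneGeometry,
    make_layout,
    sensor_view,
    zones_for,
)
from . import scenarios as sc
from .scenarios import DEFAULT_DURATIONS_S, ScenarioScript

# -- actor model --------------------------------------------------------------

STANDING = "standing"
SITTING = "sitting"
LYING = "lying"
ROLLING = "rolling"
OFF_SCENE = "off_scene"

POSTURES = (STANDING, SITTING, LYING, ROLLING, OFF_SCENE)
ON_BED_POSTURES = (SITTING, LYING, ROLLING)


@dataclass(frozen=True)
class BodyDims:
    """Cuboid body dimensions (cm)."""

    height_cm: float = 175.0
    shoulder_cm: float = 50.0
    depth_cm: float = 44.0  # torso footprint side when standing (top view)
    lying_thickness_cm: float = 25.0
    sitting_height_cm: float = 85.0  # torso top above the seat surface
    lying_length_cm: float = 170.0


@dataclass(frozen=True)
class ActorState:
    """One actor at one frame: planar position, posture, and gross motion."""

    name: str
    role: str  # subject | caregiver | visitor
    x_cm: float
    y_cm: float
    posture: str
    moving: bool = False
    dims: BodyDims = field(default_factory=BodyDims)
    bed: BedGeometry | None = None  # the bed the actor sits/lies on

    @property
    def off_scene(self) -> bool:
        return self.posture == OFF_SCENE

    def footprint(self) -> Rect | None:
        """Top-view rectangle the body occupies, or None when off-scene."""
        if self.off_scene:
            return None
        d = self.dims
        if self.posture == STANDING:
            return Rect.centred(self.x_cm, self.y_cm, d.depth_cm, d.depth_cm)
        if self.posture == SITTING:
            return Rect.centred(self.x_cm, self.y_cm, d.shoulder_cm, d.shoulder_cm)
        # lying/rolling: oriented along the bed's long axis
        along_y = True
        if self.bed is not None:
            along_y = self.bed.rect.height >= self.bed.rect.width
        w, h = (d.shoulder_cm, d.lying_length_cm) if along_y else (d.lying_length_cm, d.shoulder_cm)
        return Rect.centred(self.x_cm, self.y_cm, w, h)

    def top_height_cm(self) -> float:
        """Height of the body's top surface above the floor."""
        d = self.dims
        if self.posture == STANDING:
            return d.height_cm
        base = self.bed.surface_height_cm if self.bed is not None else 0.0
        if self.posture == SITTING:
            return base + d.sitting_height_cm
        return base + d.lying_thickness_cm


# -- depth rendering -----------------------------------------------------------


def render_depth(
    view: SensorView,
    layout: RoomLayout,
    actors: dict[str, ActorState] | tuple[ActorState, ...] = (),
    noise_sd_cm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one 512x424 depth frame (cm) for a sensor footprint.

    Surfaces are the floor (height 0), bed rectangles, and actor cuboids; each
    pixel reads the sensor distance of the tallest surface under it.  Gaussian
    noise of ``noise_sd_cm`` is added and depths are clamped to [0, D_floor].
    """
    states = actors.values() if isinstance(actors, dict) else actors
    heights = np.zeros((view.height, view.width), dtype=np.float32)
    for bed in layout.beds:
        if bed.rect.intersects(view.footprint):
            rs, cs = view.rect_slices(bed.rect)
            np.maximum(heights[rs, cs], bed.surface_height_cm, out=heights[rs, cs])
    for a in states:
        fp = a.footprint()
        if fp is None:
            continue
        if a.x_cm < layout.room.x0 or a.x_cm > layout.room.x1 or \
           a.y_cm < layout.room.y0 or a.y_cm > layout.room.y1:
            raise ValueError(f"actor {a.name} at ({a.x_cm}, {a.y_cm}) outside room")
        if fp.intersects(view.footprint):
            rs, cs = view.rect_slices(fp.clip_to(view.footprint))
            np.maximum(heights[rs, cs], a.top_height_cm(), out=heights[rs, cs])
    depth = view.sensor_height_cm - heights
    if noise_sd_cm > 0:
        if rng is None:
            rng = np.random.default_rng()
        depth = depth + rng.normal(0.0, noise_sd_cm, size=depth.shape).astype(np.float32)
    return np.clip(depth, 0.0, view.sensor_height_cm).astype(np.float32)


# -- scripted actor kinematics -------------------------------------------------


@dataclass
class _Phase:
    """One phase of a step for one actor: hold a posture or walk to a target."""

    frac: float  # share of the step duration
    posture: str
    target: tuple[float, float] | None = None  # walk towards this point
    appear_at: tuple[float, float] | None = None  # enter the scene here
    moving: bool = False  # gross body motion while holding (corrupts the radar)
    lateral_roll: bool = False
    off_at_end: bool = False


class _SceneContext:
    """Named locations for one subject's bed within a layout."""

    def __init__(self, layout: RoomLayout, bed_index: int):
        self.layout = layout
        self.bed_index = bed_index
        self.bed = layout.beds[bed_index]
        self.bedside = self.bed.exit_face_centre(offset_cm=30.0)
        self.edge_on = self.bed.exit_face_centre(offset_cm=0.0)
        self.centre = self.bed.rect.centre
        self.door = layout.door_cm
        self.toilet = layout.toilet_cm
        other = 1 - bed_index
        if layout.n_beds > 1:
            self.other_bedside = layout.beds[other].exit_face_centre(offset_cm=30.0)
        else:
            self.other_bedside = self.toilet

    def caregiver_spot(self) -> tuple[float, float]:
        # the caregiver stands a little along the bed from the subject's exit spot
        x, y = self.bedside
        return (x, y + 55.0)


def _phases_for(action: str, ctx: _SceneContext) -> dict[str, list[_Phase]]:
    """Per-actor phase plan of one scripted action."""
    plans: dict[str, list[_Phase]] = {}
    if action == sc.WALK_IN:
        plans["subject"] = [_Phase(1.0, STANDING, target=ctx.bedside, appear_at=ctx.door)]
    elif action == sc.WALK_IN_ASSISTED:
        plans["subject"] = [_Phase(1.0, STANDING, target=ctx.bedside, appear_at=ctx.door)]
        plans["caregiver"] = [
            _Phase(1.0, STANDING, target=ctx.caregiver_spot(), appear_at=ctx.door)
        ]
    elif action == sc.SIT_EDGE:
        plans["subject"] = [
            _Phase(0.4, STANDING, target=ctx.edge_on),
            _Phase(0.6, SITTING, moving=True),
        ]
    elif action == sc.MOVE_CENTRE:
        plans["subject"] = [_Phase(1.0, SITTING, target=ctx.centre, moving=True)]
    elif action in (sc.LIE, sc.COVER_QUILT, sc.WAKE, sc.FLIP_QUILT,
                    sc.BREATHE_DIFFICULTY, sc.ITCHY_THROAT):
        plans["subject"] = [_Phase(1.0, LYING, moving=True)]
    elif action == sc.SLEEP:
        plans["subject"] = [_Phase(1.0, LYING, moving=False)]
    elif action == sc.ROLL:
        plans["subject"] = [_Phase(1.0, ROLLING, moving=True, lateral_roll=True)]
    elif action in (sc.SIT_UP, sc.DRINK, sc.USE_DEVICE, sc.SNEEZE, sc.COUGH):
        plans["subject"] = [_Phase(1.0, SITTING, target=ctx.centre, moving=True)]
    elif action == sc.MOVE_EDGE:
        plans["subject"] = [_Phase(1.0, SITTING, target=ctx.edge_on, moving=True)]
    elif action == sc.STAND_UP:
        plans["subject"] = [_Phase(1.0, STANDING, target=ctx.bedside, moving=True)]
    elif action == sc.LEAVE_BED:
        plans["subject"] = [_Phase(1.0, STANDING, target=ctx.door, off_at_end=True)]
    elif action == sc.LEAVE_BED_VIA_OTHER_ZONE:
        plans["subject"] = [
            _Phase(0.5, STANDING, target=ctx.other_bedside),
            _Phase(0.15, STANDING, moving=True),
            _Phase(0.35, STANDING, target=ctx.toilet, off_at_end=True),
        ]
    elif action == sc.CAREGIVER_CHECK:
        plans["caregiver"] = [
            _Phase(0.5, STANDING, target=ctx.caregiver_spot(), appear_at=ctx.door),
            _Phase(0.5, STANDING, moving=True),
        ]
    elif action == sc.CAREGIVER_LEAVE:
        plans["caregiver"] = [_Phase(1.0, STANDING, target=ctx.door, off_at_end=True)]
    elif action == sc.VISITOR_CHECK:
        plans["visitor"] = [
            _Phase(0.6, STANDING, target=ctx.caregiver_spot(), appear_at=ctx.door),
            _Phase(0.4, STANDING, moving=True),
        ]
    elif action == sc.VISITOR_LEAVE:
        plans["visitor"] = [_Phase(1.0, STANDING, target=ctx.door, off_at_end=True)]
    elif action in (sc.CAREGIVER_CHECK_BOTH, sc.VISITOR_CHECK_BOTH):
        role = "caregiver" if action == sc.CAREGIVER_CHECK_BOTH else "visitor"
        plans[role] = [
            _Phase(0.3, STANDING, target=ctx.caregiver_spot(), appear_at=ctx.door),
            _Phase(0.15, STANDING, moving=True),
            _Phase(0.25, STANDING, target=ctx.other_bedside),
            _Phase(0.1, STANDING, moving=True),
            _Phase(0.2, STANDING, target=ctx.door, off_at_end=True),
        ]
    else:  # pragma: no cover - guarded by scenario compilation
        raise ValueError(f"unknown action {action!r}")
    return plans


@dataclass
class ActorTimeline:
    """Per-frame actor states of one scripted scenario run."""

    frames: list[dict[str, ActorState]]
    times_s: np.ndarray
    step_of_frame: np.ndarray
    step_start_s: np.ndarray  # start time of each step
    script: ScenarioScript
    bed_index: int

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def simulate_actors(
    script: ScenarioScript,
    layout: RoomLayout,
    seed: int,
    bed_index: int = 0,
    durations_s: dict[str, float] | list[float] | None = None,
    duration_jitter: float = 0.2,
    fps: int = FPS,
    actor_suffix: str = "",
    subject_dims: BodyDims | None = None,
) -> ActorTimeline:
    """Play a scenario script as continuous actor trajectories at 6 frames/s.

    ``durations_s`` overrides the per-action defaults either as a mapping
    (action -> seconds) or one value per step; otherwise defaults with
    seeded +/-``duration_jitter`` relative jitter apply.  The same seed and
    script always reproduce the identical series.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), bed_index]))
    ctx = _SceneContext(layout, bed_index)
    dims = {
        "subject": subject_dims or BodyDims(),
        "caregiver": BodyDims(height_cm=168.0),
        "visitor": BodyDims(height_cm=165.0),
    }

    step_secs: list[float] = []
    for i, step in enumerate(script.steps):
        if isinstance(durations_s, list):
            d = float(durations_s[i])
        elif isinstance(durations_s, dict) and step.action in durations_s:
            d = float(durations_s[step.action])
        else:
            d = DEFAULT_DURATIONS_S[step.action]
            if duration_jitter > 0:
                d *= 1.0 + rng.uniform(-duration_jitter, duration_jitter)
        if d <= 0:
            raise ValueError("step durations must be positive")
        step_secs.append(d)

    for pt in (ctx.door, ctx.toilet, ctx.bedside):
        if not layout.room.contains_point(*pt):
            raise ValueError(f"step target {pt} outside room")

    # current actor states (off-scene until they first appear)
    sx, sy = ctx.door
    current: dict[str, ActorState] = {
        role + actor_suffix: ActorState(
            name=role + actor_suffix, role=role, x_cm=sx, y_cm=sy,
            posture=OFF_SCENE, dims=dims[role],
        )
        for role in ("subject", "caregiver", "visitor")
    }

    frames: list[dict[str, ActorState]] = []
    step_of_frame: list[int] = []
    step_start: list[float] = []
    t0 = 0.0
    for step, secs in zip(script.steps, step_secs):
        step_start.append(t0)
        n = max(1, int(round(secs * fps)))
        plans = _phases_for(step.action, ctx)
        # fixed per-step walk jitter amplitude
        jitter_amp = float(rng.uniform(0.5, 2.0))
        jitter_phase = float(rng.uniform(0, 2 * math.pi))
        roll_amp = float(rng.uniform(5.0, 9.0))

        # resolve phase boundaries in frames for each planned actor
        resolved: dict[str, list[tuple[int, int, _Phase, tuple[float, float]]]] = {}
        for role, phases in plans.items():
            name = role + actor_suffix
            spans = []
            f0 = 0
            pos = (current[name].x_cm, current[name].y_cm)
            for k, ph in enumerate(phases):
                f1 = n if k == len(phases) - 1 else min(n, f0 + max(1, int(round(ph.frac * n))))
                start = ph.appear_at if (current[name].off_scene and ph.appear_at) else pos
                spans.append((f0, f1, ph, start))
                pos = ph.target if ph.target is not None else start
                f0 = f1
            resolved[name] = spans

        for i in range(n):
            for role, spans in resolved.items():
                name = role
                st = current[name]
                for (f0, f1, ph, start) in spans:
                    if f0 <= i < f1:
                        if ph.target is not None:
                            frac = (i + 1 - f0) / max(1, f1 - f0)
                            x = start[0] + (ph.target[0] - start[0]) * frac
                            y = start[1] + (ph.target[1] - start[1]) * frac
                            # small perpendicular sway while walking
                            if ph.posture == STANDING and (start != ph.target):
                                sway = jitter_amp * math.sin(
                                    jitter_phase + 2 * math.pi * 1.2 * (i - f0) / fps
                                )
                                dx, dy = ph.target[0] - start[0], ph.target[1] - start[1]
                                norm = math.hypot(dx, dy) or 1.0
                                x += -dy / norm * sway
                                y += dx / norm * sway
                            walking = (abs(x - st.x_cm) + abs(y - st.y_cm)) > 0.5
                            st = replace(
                                st, x_cm=x, y_cm=y, posture=ph.posture,
                                moving=walking or ph.moving,
                                bed=ctx.bed if ph.posture in ON_BED_POSTURES else None,
                            )
                        else:
                            x, y = start
                            if ph.lateral_roll:
                                # roll: lateral oscillation across the bed, staying inside it
                                x = ctx.centre[0] + roll_amp * math.sin(
                                    2 * math.pi * (i - f0 + 1) / max(6, f1 - f0)
                                )
                                y = ctx.centre[1]
                            st = replace(
                                st, x_cm=x, y_cm=y, posture=ph.posture, moving=ph.moving,
                                bed=ctx.bed if ph.posture in ON_BED_POSTURES else None,
                            )
                        if ph.off_at_end and i == f1 - 1:
                            st = replace(st, posture=OFF_SCENE, moving=False, bed=None)
                        current[name] = st
                        break
            frames.append(dict(current))
            step_of_frame.append(step.index)
        t0 += n / fps

    times = np.arange(len(frames)) / fps
    return ActorTimeline(
        frames=frames,
        times_s=times,
        step_of_frame=np.asarray(step_of_frame),
        step_start_s=np.asarray(step_start),
        script=script,
        bed_index=bed_index,
    )


# -- ultrawideband respiration radar ------------------------------------------


@dataclass
class BpmSeries:
    """Per-second breaths-per-minute series from the bedside radar.

    ``bpm`` is 0 when nobody is within the radar footprint; ``corrupted`` marks
    seconds where gross body motion in the footprint prevents a valid rate (the
    radar still confirms presence on those seconds).
    """

    seconds: np.ndarray
    bpm: np.ndarray
    corrupted: np.ndarray

    def at(self, t_s: float) -> tuple[float, bool]:
        i = min(int(t_s), len(self.bpm) - 1)
        return float(self.bpm[i]), bool(self.corrupted[i])


def simulate_uwb(
    timeline_frames: list[dict[str, ActorState]],
    radar_footprint: Rect,
    bed: BedGeometry,
    seed: int,
    nominal_bpm: float = 14.0,
    bpm_sd: float = 0.6,
    fps: int = FPS,
) -> BpmSeries:
    """Simulate the per-second breathing-rate output of one bed's radar.

    A resting (lying or sitting, still) occupant of the footprint yields a rate
    around ``nominal_bpm``; gross motion in the footprint marks the second as
    motion-corrupted; an empty footprint yields 0.
    """
    if not radar_footprint.contains_rect(bed.rect):
        raise ValueError("radar footprint must cover the bed rectangle")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 9137]))
    n_seconds = max(1, math.ceil(len(timeline_frames) / fps))
    bpm = np.zeros(n_seconds)
    corrupted = np.zeros(n_seconds, dtype=bool)
    for s in range(n_seconds):
        chunk = timeline_frames[s * fps:(s + 1) * fps] or timeline_frames[-1:]
        occupied = False
        motion = False
        resting = False
        for states in chunk:
            for a in states.values():
                fp = a.footprint()
                if fp is None or not fp.intersects(radar_footprint):
                    continue
                occupied = True
                if a.posture == STANDING or a.moving:
                    motion = True
                elif a.posture in (LYING, SITTING, ROLLING):
                    resting = True
        if not occupied:
            continue
        if motion or not resting:
            corrupted[s] = True
        else:
            bpm[s] = max(1.0, nominal_bpm + rng.normal(0.0, bpm_sd))
    return BpmSeries(seconds=np.arange(n_seconds, dtype=float), bpm=bpm, corrupted=corrupted)


#: how far beyond the bed rectangle the radar still senses a body (cm)
RADAR_MARGIN_CM = 35.0


def radar_footprint_for(bed: BedGeometry, room: Rect) -> Rect:
    return bed.rect.dilate(RADAR_MARGIN_CM).clip_to(room)


# -- ground truth --------------------------------------------------------------


@dataclass(frozen=True)
class ExitEvent:
    timestamp_s: float
    actor: str
    move_index: int


@dataclass(frozen=True)
class MoveWindow:
    """One scenario move: its observation window and the true exit time."""

    move_index: int
    start_s: float
    end_s: float
    exit_time_s: float


@dataclass
class GroundTruthLog:
    """Observer record for one bed in one trial."""

    scenario_id: str
    events: tuple[ExitEvent, ...]
    moves: tuple[MoveWindow, ...]

    def __post_init__(self) -> None:
        ts = [e.timestamp_s for e in self.events]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("ground-truth timestamps must be strictly increasing")

    @property
    def n_exits(self) -> int:
        return len(self.events)


def _extract_ground_truth(
    timeline: ActorTimeline,
    zones: ZoneGeometry,
    subject_name: str,
    offset_s: float,
    fps: int = FPS,
    min_inside_s: float = 5.0,
) -> GroundTruthLog:
    """Bed-exit events: the subject's centre leaves the leave zone after having
    been inside it for at least ``min_inside_s`` (hysteresis against jitter)."""
    events: list[ExitEvent] = []
    inside_since: float | None = None
    for i, states in enumerate(timeline.frames):
        a = states[subject_name]
        t = offset_s + i / fps
        inside = (not a.off_scene) and zones.leave_zone.contains_point(a.x_cm, a.y_cm)
        if inside:
            if inside_since is None:
                inside_since = t
        else:
            if inside_since is not None and t - inside_since >= min_inside_s:
                events.append(ExitEvent(timestamp_s=t, actor=subject_name,
                                        move_index=len(events)))
            inside_since = None

    script = timeline.script
    move_bounds = [offset_s + timeline.step_start_s[k] for k in script.move_starts[1:]]
    end = offset_s + timeline.n_frames / fps
    starts = [0.0] + move_bounds
    ends = move_bounds + [end]
    if len(events) != script.expected_exits:
        raise RuntimeError(
            f"{script.scenario_id}: simulated {len(events)} exits, "
            f"expected {script.expected_exits}"
        )
    moves = tuple(
        MoveWindow(move_index=k, start_s=s, end_s=e, exit_time_s=events[k].timestamp_s)
        for k, (s, e) in enumerate(zip(starts, ends))
    )
    return GroundTruthLog(scenario_id=script.scenario_id, events=tuple(events), moves=moves)


# -- one trial ------------------------------------------------------------------


@dataclass
class Trial:
    """One simulated trial: merged actor series plus per-bed sensor channels.

    Depth frames are rendered lazily (`iter_frames`) and deterministically from
    the trial seed, so a trial of any length needs only the actor series in
    memory.
    """

    layout: RoomLayout
    scripts: tuple[ScenarioScript, ...]
    seed: int
    noise_sd_cm: float
    fps: int
    actor_frames: list[dict[str, ActorState]]
    times_s: np.ndarray
    zones: tuple[ZoneGeometry, ...]
    views: tuple[SensorView, ...]
    bpm: tuple[BpmSeries, ...]
    truth: tuple[GroundTruthLog, ...]
    lead_in_frames: int

    @property
    def n_frames(self) -> int:
        return len(self.actor_frames)

    def iter_frames(self, bed_index: int = 0):
        """Yield (timestamp_s, depth array) for one bed's sensor."""
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31), 7001 + bed_index])
        )
        view = self.views[bed_index]
        for i, states in enumerate(self.actor_frames):
            yield self.times_s[i], render_depth(
                view, self.layout, states, noise_sd_cm=self.noise_sd_cm, rng=rng
            )


def run_trial(
    scripts: ScenarioScript | list[ScenarioScript] | tuple[ScenarioScript, ...],
    layout: RoomLayout,
    seed: int,
    noise_sd_cm: float = 1.0,
    lead_in_s: float = 5.5,
    durations_s: dict[str, float] | None = None,
    duration_jitter: float = 0.2,
    nominal_bpm: tuple[float, ...] = (14.0, 15.0),
) -> Trial:
    """Simulate one full trial: actors, radar series, and ground truth.

    A double layout requires one script per bed (run concurrently).  The frame
    stream starts with ``lead_in_s`` of motion-free empty-room frames so the
    pipeline can acquire its stationary background.
    """
    if isinstance(scripts, ScenarioScript):
        scripts = (scripts,)
    scripts = tuple(scripts)
    if layout.n_beds != len(scripts):
        raise ValueError(f"{layout.preset} layout requires {layout.n_beds} script(s)")
    fps = FPS
    timelines = [
        simulate_actors(
            s, layout, seed=seed + 97 * b, bed_index=b,
            durations_s=durations_s, duration_jitter=duration_jitter,
            actor_suffix=f"_{b}",
        )
        for b, s in enumerate(scripts)
    ]

    lead_n = int(round(lead_in_s * fps))
    n = lead_n + max(t.n_frames for t in timelines)
    empty: dict[str, ActorState] = {}
    merged: list[dict[str, ActorState]] = []
    for i in range(n):
        states: dict[str, ActorState] = {}
        for tl in timelines:
            j = i - lead_n
            if j < 0:
                continue
            frame = tl.frames[min(j, tl.n_frames - 1)]
            if j >= tl.n_frames:  # script finished: freeze, no motion
                frame = {k: replace(v, moving=False) for k, v in frame.items()}
            states.update(frame)
        merged.append(states or dict(empty))

    zones = tuple(zones_for(layout, b) for b in range(layout.n_beds))
    views = tuple(sensor_view(layout, b) for b in range(layout.n_beds))
    bpm = tuple(
        simulate_uwb(
            merged, radar_footprint_for(layout.beds[b], layout.room), layout.beds[b],
            seed=seed + 31 * b,
            nominal_bpm=nominal_bpm[b % len(nominal_bpm)],
        )
        for b in range(layout.n_beds)
    )
    truth = tuple(
        _extract_ground_truth(
            timelines[b], zones[b], subject_name=f"subject_{b}",
            offset_s=lead_n / fps,
        )
        for b in range(layout.n_beds)
    )
    # extend the first move window back to the trial start
    truth = tuple(
        GroundTruthLog(
            scenario_id=t.scenario_id,
            events=t.events,
            moves=tuple(
                MoveWindow(m.move_index, 0.0 if m.move_index == 0 else m.start_s,
                           m.end_s if m.move_index < len(t.moves) - 1 else n / fps,
                           m.exit_time_s)
                for m in t.moves
            ),
        )
        for t in truth
    )
    return Trial(
        layout=layout,
        scripts=scripts,
        seed=int(seed),
        noise_sd_cm=noise_sd_cm,
        fps=fps,
        actor_frames=merged,
        times_s=np.arange(n) / fps,
        zones=zones,
        views=views,
        bpm=bpm,
        truth=truth,
        lead_in_frames=lead_n,
    )


# -- experiment schedules --------------------------------------------------------


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: participating subject ids and their scenarios."""

    subjects: tuple[int, ...]
    scenario_ids: tuple[str, ...]
    seed: int

    @property
    def expected_moves(self) -> int:
        return sum(2 if s == "Sc3" else 1 for s in self.scenario_ids)


@dataclass
class ExperimentPlan:
    setting: str
    trials: list[TrialSpec]
    expected_moves: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def schedule_experiment(
    setting: str,
    n_subjects: int,
    n_trials: int = 3,
    seed: int = 0,
) -> ExperimentPlan:
    """Build the trial schedule of the evaluation protocol.

    Single setting: every subject performs each of the 9 scenarios ``n_trials``
    times in a per-subject randomised order; Sc3 contributes two bed-exit
    moves, so the expected move total is ``n_subjects * n_trials * 10``.

    Double setting: subjects come in pairs; each pair covers all 45 unordered
    scenario combinations ``n_trials`` times (the member performing each half
    of a combination is randomised), giving ``n_trials * (45*2 + 10)`` moves
    per pair — 300 for three rounds.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 551]))
    trials: list[TrialSpec] = []
    if setting == "single":
        for subj in range(n_subjects):
            order = np.repeat(np.arange(9), n_trials)
            rng.shuffle(order)
            for k in order:
                trials.append(TrialSpec(
                    subjects=(subj,),
                    scenario_ids=(sc.SCENARIO_IDS[int(k)],),
                    seed=int(rng.integers(0, 2**31 - 1)),
                ))
        expected = n_subjects * n_trials * 10
    elif setting == "double":
        if n_subjects % 2 != 0:
            raise ValueError("double setting requires an even subject count (pairs)")
        combos = [(i, j) for i in range(9) for j in range(i, 9)]  # 45 unordered
        for p in range(n_subjects // 2):
            subj_a, subj_b = 2 * p, 2 * p + 1
            plan = [(i, j) for _ in range(n_trials) for (i, j) in combos]
            rng.shuffle(plan)
            for (i, j) in plan:
                if rng.random() < 0.5:
                    i, j = j, i
                trials.append(TrialSpec(
                    subjects=(subj_a, subj_b),
                    scenario_ids=(sc.SCENARIO_IDS[i], sc.SCENARIO_IDS[j]),
                    seed=int(rng.integers(0, 2**31 - 1)),
                ))
        expected = (n_subjects // 2) * n_trials * (45 * 2 + 10)
    else:
        raise ValueError(f"unknown setting {setting!r}")
    assert sum(t.expected_moves for t in trials) == expected
    return ExperimentPlan(setting=setting, trials=trials, expected_moves=expected)
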