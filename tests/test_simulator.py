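"""Actor kinematics, depth rendering, radar simulation, trials, schedules."""

import numpy as np
import pytest

import enightlog as en
from enightlog import scenarios as sc
from enightlog.simulator import (
    LYING,
    OFF_SCENE,
    ROLLING,
    radar_footprint_for,
    simulate_actors,
    simulate_uwb,
)
from conftest import lying_subject


# -- kinematics ---------------------------------------------------------------


def test_fixed_durations_give_expected_frame_count(single_layout):
    script = en.compile_scenario("Sc1")
    tl = simulate_actors(script, single_layout, seed=0,
                         durations_s=[2.0] * script.n_steps)
    assert tl.n_frames == 12 * 2 * 6


def test_actor_series_deterministic(single_layout):
    script = en.compile_scenario("Sc2")
    a = simulate_actors(script, single_layout, seed=42)
    b = simulate_actors(script, single_layout, seed=42)
    assert a.n_frames == b.n_frames
    for fa, fb in zip(a.frames, b.frames):
        assert fa == fb


def test_no_teleporting(single_layout):
    script = en.compile_scenario("Sc7")
    tl = simulate_actors(script, single_layout, seed=5)
    prev = {}
    for states in tl.frames:
        for name, a in states.items():
            if name in prev and not a.off_scene and not prev[name].off_scene:
                d = np.hypot(a.x_cm - prev[name].x_cm, a.y_cm - prev[name].y_cm)
                assert d <= 50.0
            prev[name] = a


def test_sc2_rolling_stays_in_bed(single_layout):
    tl = simulate_actors(en.compile_scenario("Sc2"), single_layout, seed=9)
    bed = single_layout.beds[0].rect
    rolling = [s["subject"] for s in tl.frames if s["subject"].posture == ROLLING]
    assert rolling, "Sc2 must contain a rolling interval"
    # exactly one maximal rolling interval
    runs = 0
    prev = False
    for s in tl.frames:
        now = s["subject"].posture == ROLLING
        runs += int(now and not prev)
        prev = now
    assert runs == 1
    for a in rolling:
        assert bed.contains_rect(a.footprint())


# -- depth rendering ----------------------------------------------------------


def test_static_scene_renders_floor_and_bed(single_layout, single_view):
    frame = en.render_depth(single_view, single_layout)
    assert frame.shape == (424, 512)
    assert set(np.unique(frame)) == {270.0 - 55.0, 270.0}


def test_lying_subject_depth(single_layout, single_view):
    frame = en.render_depth(single_view, single_layout, (lying_subject(single_layout),))
    rs, cs = single_view.rect_slices(single_layout.beds[0].rect)
    assert frame[rs, cs].min() == 270.0 - 55.0 - 25.0  # 190 cm over the torso


def test_standing_subject_depth(single_layout, single_view):
    st = en.ActorState(name="s", role="subject", x_cm=200.0, y_cm=150.0,
                       posture="standing")
    frame = en.render_depth(single_view, single_layout, (st,))
    assert frame.min() == 270.0 - 175.0  # head of a 175 cm subject


def test_occlusion_matches_bruteforce_oracle(single_layout, single_view):
    """Per-pixel depth equals the minimum candidate surface distance."""
    bed = single_layout.beds[0]
    actors = (
        lying_subject(single_layout),
        en.ActorState(name="c", role="caregiver", x_cm=330.0, y_cm=150.0,
                      posture="standing", dims=en.BodyDims(height_cm=168.0)),
    )
    frame = en.render_depth(single_view, single_layout, actors)
    surfaces = [(bed.rect, bed.surface_height_cm)] + [
        (a.footprint(), a.top_height_cm()) for a in actors
    ]
    rng = np.random.default_rng(3)
    rows = rng.integers(0, 424, 32)
    cols = rng.integers(0, 512, 32)
    for r in rows:
        for c in cols:
            x, y = single_view.col_x_cm[c], single_view.row_y_cm[r]
            h = max([0.0] + [hh for rect, hh in surfaces
                             if rect.x0 <= x < rect.x1 and rect.y0 <= y < rect.y1])
            assert frame[r, c] == pytest.approx(270.0 - h)


def test_render_deterministic_under_noise(single_layout, single_view):
    rngs = [np.random.default_rng(7) for _ in range(2)]
    frames = [
        en.render_depth(single_view, single_layout, (lying_subject(single_layout),),
                        noise_sd_cm=1.0, rng=r)
        for r in rngs
    ]
    assert np.array_equal(frames[0], frames[1])
    assert frames[0].max() <= 270.0 and frames[0].min() >= 0.0


# -- respiration radar --------------------------------------------------------


def _uwb_for_frames(layout, frames, seed=0, nominal=14.0):
    bed = layout.beds[0]
    return simulate_uwb(frames, radar_footprint_for(bed, layout.room), bed,
                        seed=seed, nominal_bpm=nominal)


def test_uwb_empty_bed_reads_zero(single_layout):
    frames = [{} for _ in range(60)]
    s = _uwb_for_frames(single_layout, frames)
    assert (s.bpm == 0).all() and not s.corrupted.any()


def test_uwb_resting_subject_rate(single_layout):
    sub = lying_subject(single_layout)
    frames = [{"subject_0": sub} for _ in range(60 * 6)]
    s = _uwb_for_frames(single_layout, frames, nominal=14.0)
    assert abs(s.bpm.mean() - 14.0) <= 2.0
    assert (s.bpm > 0).all()


def test_uwb_walking_subject_is_motion_corrupted(single_layout):
    bed = single_layout.beds[0]
    x0, y0 = bed.exit_face_centre(offset_cm=10.0)
    frames = [
        {"subject_0": en.ActorState(name="subject_0", role="subject",
                                    x_cm=x0, y_cm=y0, posture="standing",
                                    moving=True)}
        for _ in range(18)
    ]
    s = _uwb_for_frames(single_layout, frames)
    assert s.corrupted.all()
    assert (s.bpm == 0).all()  # no valid rate while moving


# -- trials -------------------------------------------------------------------


@pytest.mark.parametrize("sid,n_exits", [("Sc1", 1), ("Sc3", 2)])
def test_trial_ground_truth_counts(single_layout, sid, n_exits):
    trial = en.run_trial(en.compile_scenario(sid), single_layout, seed=13,
                         noise_sd_cm=0.0)
    assert trial.truth[0].n_exits == n_exits
    ts = [e.timestamp_s for e in trial.truth[0].events]
    assert ts == sorted(ts)


def test_double_trial_total_exits(double_layout):
    scripts = [en.compile_scenario("Sc3", "double"),
               en.compile_scenario("Sc7", "double")]
    trial = en.run_trial(scripts, double_layout, seed=13, noise_sd_cm=0.0)
    assert sum(t.n_exits for t in trial.truth) == 3


def test_trial_starts_with_motion_free_leadin(sc1_trial):
    assert sc1_trial.lead_in_frames >= 30
    it = sc1_trial.iter_frames(0)
    _, first = next(it)
    for _ in range(sc1_trial.lead_in_frames - 1):
        _, f = next(it)
        assert np.array_equal(f, first)  # noiseless empty room is static


def test_trial_frames_deterministic(single_layout):
    trials = [en.run_trial(en.compile_scenario("Sc1"), single_layout, seed=3,
                           noise_sd_cm=1.0) for _ in range(2)]
    for (t0, f0), (t1, f1) in zip(*(t.iter_frames(0) for t in trials)):
        assert t0 == t1
        assert np.array_equal(f0, f1)


def test_double_layout_requires_two_scripts(double_layout):
    with pytest.raises(ValueError):
        en.run_trial(en.compile_scenario("Sc1"), double_layout, seed=0)


# -- schedules ----------------------------------------------------------------


def test_single_schedule_bookkeeping():
    plan = en.schedule_experiment("single", 30, 3, seed=0)
    assert len(plan.trials) == 810
    assert plan.expected_moves == 900


def test_double_schedule_bookkeeping():
    plan = en.schedule_experiment("double", 30, 3, seed=0)
    assert plan.expected_moves == 4500
    per_pair = {}
    for t in plan.trials:
        per_pair.setdefault(t.subjects, 0)
        per_pair[t.subjects] += t.expected_moves
    assert all(v == 300 for v in per_pair.values())
    assert len(per_pair) == 15


def test_minimal_single_schedule():
    plan = en.schedule_experiment("single", 1, 1, seed=5)
    assert len(plan.trials) == 9
    assert plan.expected_moves == 10  # nine scenarios plus the second Sc3 exit


@pytest.mark.parametrize("n,k", [(1, 1), (2, 3), (5, 2)])
def test_schedule_move_conservation(n, k):
    assert en.schedule_experiment("single", n, k, seed=1).expected_moves == n * k * 10
    assert (en.schedule_experiment("double", 2 * n, k, seed=1).expected_moves
            == n * k * (2 * 45 + 10))


def test_double_schedule_covers_all_45_combinations():
    plan = en.schedule_experiment("double", 2, 1, seed=2)
    combos = {tuple(sorted(t.scenario_ids)) for t in plan.trials}
    assert len(plan.trials) == 45
    assert len(combos) == 45


def test_odd_subject_count_rejected_for_double():
    with pytest.raises(ValueError):
        en.schedule_experiment("double", 3, 1, seed=0)
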