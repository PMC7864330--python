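"""Event-level evaluation: confusion counts, the four metrics, experiments.

Every scenario move contributes exactly one positive opportunity (the true
bed-exit) and one negative opportunity (its false-alarm window): a detection
within the match window of the true exit scores a TP (else FN); any unmatched
detection inside the move's window scores one FP — multiple false alarms on a
single move still count once — otherwise the move scores a TN.  This counting
rule makes TP+FN and TN+FP each equal the scheduled move total.

The four detection metrics, in percent:

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    precision   = TP / (TP + FP) * 100

rounded half-up to one decimal.  ``run_experiment`` executes a scheduled
experiment end-to-end (simulate -> pipeline -> classify -> match) for the
depth-camera system and, in the single-bed setting, the pressure-mat +
infrared-fence baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cbd import cbd_detect, simulate_cbd_trace
from .classifier import (
    Alarm,
    State,
    StateRecord,
    ThresholdSet,
    extract_exit_events,
    run_classifier,
)
from .config import Config
from .geometry import ZoneMasks, make_layout
from .pipeline import DepthFrame, acquire_background, extract_features
from .simulator import (
    GroundTruthLog,
    LYING,
    ROLLING,
    SITTING,
    Trial,
    run_trial,
    schedule_experiment,
)
from .scenarios import compile_scenario


@dataclass
class ConfusionCounts:
    """Event-level confusion counts."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def match_events(
    detected: list[float],
    truth: GroundTruthLog,
    match_window_s: float = 10.0,
) -> ConfusionCounts:
    """Score detections against the ground truth, per scenario move.

    A move's exit is detected (TP) if at least one detection falls within
    ``match_window_s`` of the true exit time; each detection can match only
    one exit.  Independently, a move scores a single FP if any unmatched
    detection fell inside its observation window, else a TN.
    """
    if match_window_s <= 0:
        raise ValueError("match window must be positive")
    moves = sorted(truth.moves, key=lambda m: m.start_s)
    for a, b in zip(moves, moves[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValueError("overlapping move windows in the ground truth")

    detected = sorted(detected)
    matched: set[int] = set()
    counts = ConfusionCounts()
    for m in moves:
        hit = None
        for i, d in enumerate(detected):
            if i not in matched and abs(d - m.exit_time_s) <= match_window_s:
                hit = i
                break
        if hit is None:
            counts.fn += 1
        else:
            matched.add(hit)
            counts.tp += 1
    for m in moves:
        false_alarm = any(
            m.start_s <= d < m.end_s
            for i, d in enumerate(detected)
            if i not in matched
        )
        if false_alarm:
            counts.fp += 1
        else:
            counts.tn += 1
    return counts


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """The four detection metrics (percent, one decimal) plus their counts.

    A metric whose denominator is zero is reported as None (undefined), never
    as 0.
    """

    counts: ConfusionCounts
    system: str = ""
    setting: str = ""

    def _pct(self, num: int, den: int) -> float | None:
        if den == 0:
            return None
        return _round1(100.0 * num / den)

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.counts.tp, self.counts.tp + self.counts.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.counts.tn, self.counts.tn + self.counts.fp)

    @property
    def accuracy(self) -> float | None:
        return self._pct(self.counts.tp + self.counts.tn, self.counts.total)

    @property
    def precision(self) -> float | None:
        return self._pct(self.counts.tp, self.counts.tp + self.counts.fp)


def compute_metrics(
    counts: ConfusionCounts, system: str = "", setting: str = ""
) -> MetricsReport:
    """Wrap confusion counts into the four-metric report."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from an empty count set")
    return MetricsReport(counts=counts, system=system, setting=setting)


# -- end-to-end experiment ------------------------------------------------------


def detect_trial_events(
    trial: Trial,
    bed_index: int = 0,
    config: Config | None = None,
) -> tuple[list[float], list[StateRecord]]:
    """Run one bed's sensor stream through the full detection chain.

    Acquires the stationary background from the trial's lead-in frames, streams
    the remaining frames through feature extraction and the state machine, and
    returns the detected bed-exit timestamps with the per-frame state log.
    """
    cfg = config or Config()
    frames = trial.iter_frames(bed_index)
    lead_in = itertools.islice(frames, trial.lead_in_frames)
    background = acquire_background(
        (DepthFrame(values=v, timestamp_s=t) for t, v in lead_in),
        motion_tolerance_cm=cfg.motion_tolerance_cm,
    )
    masks = ZoneMasks.from_zones(trial.views[bed_index], trial.zones[bed_index])
    features = extract_features(
        frames,
        background,
        masks,
        trial.zones[bed_index],
        pth_motion=cfg.thresholds.pth_motion,
        foreground_threshold_cm=cfg.foreground_threshold_cm,
        bpm=trial.bpm[bed_index],
    )
    state_log = run_classifier(features, cfg.thresholds)
    return extract_exit_events(state_log), state_log


def _subject_on_bed_times(trial: Trial, bed_index: int) -> np.ndarray:
    name = f"subject_{bed_index}"
    on_bed = np.zeros(trial.n_frames, dtype=bool)
    for i, states in enumerate(trial.actor_frames):
        a = states.get(name)
        if a is not None and a.posture in (LYING, ROLLING, SITTING):
            on_bed[i] = True
    return on_bed


@dataclass
class ExperimentResult:
    """Aggregated metrics per system plus per-trial bookkeeping rows."""

    setting: str
    reports: dict[str, MetricsReport]
    trials: pd.DataFrame


def run_experiment(
    setting: str,
    system: str = "enightlog",
    n_subjects: int = 2,
    n_trials: int = 3,
    seed: int = 0,
    noise_sd_cm: float = 0.0,
    config: Config | None = None,
) -> ExperimentResult:
    """Execute a scheduled experiment end-to-end and aggregate the metrics.

    ``system`` selects ``"enightlog"``, ``"cbd"`` or ``"both"``; the baseline
    exists only in the single-bed setting.  All randomness derives from
    ``seed``.  Per-trial rows record the scenario, ground-truth and detected
    exit counts, the confusion counts, whether any caregiver/visitor frames
    were classified ``others``, and whether a red alarm was ever raised while
    the subject was on the bed.
    """
    systems = ("enightlog", "cbd") if system == "both" else (system,)
    if "cbd" in systems and setting == "double":
        raise ValueError("the pressure-mat + infrared-fence baseline is single-bed only")
    if not set(systems) <= {"enightlog", "cbd"}:
        raise ValueError(f"unknown system {system!r}")
    cfg = config or Config()
    plan = schedule_experiment(setting, n_subjects, n_trials, seed)
    layout = make_layout(setting)

    totals = {s: ConfusionCounts() for s in systems}
    rows: list[dict] = []
    for spec in plan.trials:
        scripts = [compile_scenario(sid, setting) for sid in spec.scenario_ids]
        trial = run_trial(scripts, layout, seed=spec.seed, noise_sd_cm=noise_sd_cm)
        for b in range(layout.n_beds):
            on_bed = _subject_on_bed_times(trial, b)
            if "enightlog" in systems:
                events, state_log = detect_trial_events(trial, b, cfg)
                counts = match_events(events, trial.truth[b], cfg.match_window_s)
                totals["enightlog"] += counts
                idx = np.minimum(
                    (np.array([r.timestamp_s for r in state_log]) * trial.fps).astype(int),
                    trial.n_frames - 1,
                )
                red_in_bed = any(
                    r.alarm == Alarm.RED and on_bed[i]
                    for r, i in zip(state_log, idx)
                )
                rows.append({
                    "system": "enightlog", "setting": setting,
                    "subject": spec.subjects[b if len(spec.subjects) > 1 else 0],
                    "scenario": spec.scenario_ids[b if len(spec.scenario_ids) > 1 else 0],
                    "bed": b, "seed": spec.seed,
                    "truth_exits": trial.truth[b].n_exits,
                    "detected": len(events),
                    "tp": counts.tp, "tn": counts.tn,
                    "fp": counts.fp, "fn": counts.fn,
                    "others_frames": sum(r.state == State.OTHERS for r in state_log),
                    "red_while_in_bed": red_in_bed,
                })
            if "cbd" in systems and b == 0:
                trace = simulate_cbd_trace(
                    trial.actor_frames, layout, bed_index=0, fps=trial.fps,
                    visitor_presses_mat=cfg.cbd_visitor_presses_mat,
                )
                events = cbd_detect(trace, cfg.cbd_pattern_window_s)
                counts = match_events(events, trial.truth[0], cfg.match_window_s)
                totals["cbd"] += counts
                rows.append({
                    "system": "cbd", "setting": setting,
                    "subject": spec.subjects[0], "scenario": spec.scenario_ids[0],
                    "bed": 0, "seed": spec.seed,
                    "truth_exits": trial.truth[0].n_exits,
                    "detected": len(events),
                    "tp": counts.tp, "tn": counts.tn,
                    "fp": counts.fp, "fn": counts.fn,
                    "others_frames": 0, "red_while_in_bed": False,
                })

    reports = {
        s: compute_metrics(totals[s], system=s, setting=setting) for s in systems
    }
    for s in systems:
        c = totals[s]
        if c.tp + c.fn != plan.expected_moves or c.tn + c.fp != plan.expected_moves:
            raise RuntimeError(
                f"bookkeeping violated for {s}: TP+FN={c.tp + c.fn}, "
                f"TN+FP={c.tn + c.fp}, expected {plan.expected_moves}"
            )
    return ExperimentResult(setting=setting, reports=reports, trials=pd.DataFrame(rows))


# -- reporting ------------------------------------------------------------------

_REPORT_ROWS = (
    "total", "TP", "TN", "FP", "FN",
    "accuracy", "precision", "sensitivity", "specificity",
)


def export_report(reports: list[MetricsReport] | dict[str, MetricsReport]) -> pd.DataFrame:
    """Comparison table: one column per system/setting, metric rows.

    Undefined metrics render as ``"N/A"``; percentages carry one decimal.
    """
    if isinstance(reports, dict):
        reports = list(reports.values())
    if not reports:
        raise ValueError("need at least one report")
    table: dict[str, list] = {}
    for r in reports:
        label = " ".join(x for x in (r.system, r.setting) if x) or "system"
        c = r.counts
        col = [c.total, c.tp, c.tn, c.fp, c.fn]
        for name in ("accuracy", "precision", "sensitivity", "specificity"):
            v = getattr(r, name)
            col.append("N/A" if v is None else f"{v:.1f}")
        table[label] = col
    return pd.DataFrame(table, index=list(_REPORT_ROWS))
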