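"""Streamed depth-frame processing: background, zone features, silhouettes.

At start-up the pipeline watches five seconds of the stream; if nothing moved,
the first frame becomes the stationary background ``B``.  Every subsequent
frame ``F`` is compared against ``B``: pixels whose depth changed by more than
a small tolerance are foreground, and — deliberately — keep their *original*
depth in ``F'`` rather than the difference, so that "above sleep level"
remains a plain depth comparison downstream.

From ``F'`` the per-frame zone features are counted:

* ``P_bed_zone`` — foreground pixels inside the bed zone nearer to the sensor
  than the sleep level ``D_sleep`` (a raised torso);
* ``P_leave_zone`` / ``P_boundary_zone`` — foreground pixels inside the leave
  and boundary rings;
* ``P_depth`` — their sum (each pixel falls in at most one extent).

Motion flags compare consecutive counts against a pixel-change threshold.
The silhouette renderer maps foreground depths linearly between the closest
(brightest) and farthest (darkest non-zero) detected object, which hides all
raw depths and identifying detail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np

from .geometry import FPS, FRAME_HEIGHT, FRAME_WIDTH, ZoneGeometry, ZoneMasks
from .simulator import BpmSeries

ROLE_RAW = "raw"
ROLE_BACKGROUND = "background"
ROLE_FOREGROUND = "foreground"

#: default per-pixel depth-change tolerance separating foreground from noise (cm)
DEFAULT_FOREGROUND_THRESHOLD_CM = 5.0
#: default start-up motion tolerance for background acquisition (cm): well above
#: sensor noise, far below the >=80 cm change any person in view causes
DEFAULT_MOTION_TOLERANCE_CM = 20.0
MIN_BACKGROUND_FRAMES = 30  # five seconds at 6 frames/s


class MotionDetectedError(RuntimeError):
    """Motion occurred in the background-acquisition window; caller must retry."""


@dataclass(frozen=True)
class DepthFrame:
    """One 512x424 grid of sensor-to-surface distances (cm)."""

    values: np.ndarray
    timestamp_s: float
    role: str = ROLE_RAW

    def __post_init__(self) -> None:
        if self.values.shape != (FRAME_HEIGHT, FRAME_WIDTH):
            raise ValueError(
                f"expected {FRAME_HEIGHT}x{FRAME_WIDTH} frame, got {self.values.shape}"
            )


@dataclass(frozen=True)
class FrameFeatures:
    """Zone pixel counts, motion flags, and the radar rate for one frame."""

    timestamp_s: float
    p_bed_zone: int
    p_leave_zone: int
    p_boundary_zone: int
    p_depth_prev: int = 0
    m_above_sleep_level: bool = False
    m_leave_zone: bool = False
    m_boundary_zone: bool = False
    b_bpm: float = 0.0
    b_motion: bool = False

    @property
    def p_depth(self) -> int:
        """Total foreground pixels across the three extents (Table identity)."""
        return self.p_bed_zone + self.p_leave_zone + self.p_boundary_zone


@dataclass(frozen=True)
class MotionFlags:
    above_sleep_level: bool
    leave_zone: bool
    boundary_zone: bool


def acquire_background(
    frames: Iterable[DepthFrame],
    motion_tolerance_cm: float = DEFAULT_MOTION_TOLERANCE_CM,
    min_frames: int = MIN_BACKGROUND_FRAMES,
) -> DepthFrame:
    """Watch a >=5 s window; return the first frame as background if all quiet.

    Raises :class:`MotionDetectedError` if any pixel's depth range across the
    window exceeds ``motion_tolerance_cm``, and ``ValueError`` on fewer than
    ``min_frames`` frames.
    """
    first: DepthFrame | None = None
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    n = 0
    for f in frames:
        if first is None:
            first = f
            lo = f.values.copy()
            hi = f.values.copy()
        else:
            np.minimum(lo, f.values, out=lo)
            np.maximum(hi, f.values, out=hi)
        n += 1
    if first is None or n < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {n}")
    if float(np.max(hi - lo)) > motion_tolerance_cm:
        raise MotionDetectedError(
            "motion detected in the background-acquisition window"
        )
    return replace(first, role=ROLE_BACKGROUND)


def subtract_background(
    frame: DepthFrame,
    background: DepthFrame,
    foreground_threshold_cm: float = DEFAULT_FOREGROUND_THRESHOLD_CM,
) -> DepthFrame:
    """Remove the stationary background; foreground keeps its original depth."""
    if frame.values.shape != background.values.shape:
        raise ValueError("frame and background shapes differ")
    fg = np.abs(frame.values - background.values) > foreground_threshold_cm
    return DepthFrame(
        values=np.where(fg, frame.values, 0.0).astype(np.float32),
        timestamp_s=frame.timestamp_s,
        role=ROLE_FOREGROUND,
    )


def count_zone_pixels(
    foreground: DepthFrame,
    masks: ZoneMasks,
    zones: ZoneGeometry,
) -> FrameFeatures:
    """Count foreground pixels per zone extent (bed zone: above sleep level only)."""
    v = foreground.values
    fg = v > 0
    p_bed = int(np.count_nonzero(fg & masks.bed & (v < zones.d_sleep_cm)))
    p_leave = int(np.count_nonzero(fg & masks.leave_ring))
    p_boundary = int(np.count_nonzero(fg & masks.boundary_ring))
    return FrameFeatures(
        timestamp_s=foreground.timestamp_s,
        p_bed_zone=p_bed,
        p_leave_zone=p_leave,
        p_boundary_zone=p_boundary,
    )


def detect_motion(
    curr: FrameFeatures,
    prev: FrameFeatures,
    pth_motion: int,
) -> MotionFlags:
    """Flag each zone whose pixel count changed by more than ``pth_motion``."""
    return MotionFlags(
        above_sleep_level=abs(curr.p_bed_zone - prev.p_bed_zone) > pth_motion,
        leave_zone=abs(curr.p_leave_zone - prev.p_leave_zone) > pth_motion,
        boundary_zone=abs(curr.p_boundary_zone - prev.p_boundary_zone) > pth_motion,
    )


def render_silhouette(foreground: DepthFrame) -> np.ndarray:
    """Privacy-preserving 8-bit silhouette of a foreground frame.

    Foreground depths map linearly onto grey levels 255 (closest detected
    object) down to 1 (farthest); background stays 0.  A constant-depth blob
    maps to the single brightest level.
    """
    v = foreground.values
    out = np.zeros(v.shape, dtype=np.uint8)
    fg = v > 0
    if not fg.any():
        return out
    dmin = float(v[fg].min())
    dmax = float(v[fg].max())
    if dmax == dmin:
        out[fg] = 255
        return out
    norm = (v[fg] - dmin) / (dmax - dmin)  # 0 = closest, 1 = farthest
    out[fg] = np.round(255 - norm * 254).astype(np.uint8)
    return out


def extract_features(
    frames: Iterable[tuple[float, np.ndarray]],
    background: DepthFrame,
    masks: ZoneMasks,
    zones: ZoneGeometry,
    pth_motion: int = 50,
    foreground_threshold_cm: float = DEFAULT_FOREGROUND_THRESHOLD_CM,
    bpm: BpmSeries | None = None,
) -> Iterator[FrameFeatures]:
    """Stream (timestamp, depth array) pairs into per-frame features.

    Attaches the radar's breaths-per-minute sample of the current second and
    the motion flags relative to the previous frame.
    """
    prev: FrameFeatures | None = None
    for t, values in frames:
        fprime = subtract_background(
            DepthFrame(values=values, timestamp_s=t), background,
            foreground_threshold_cm=foreground_threshold_cm,
        )
        feats = count_zone_pixels(fprime, masks, zones)
        if bpm is not None:
            rate, corrupted = bpm.at(t)
            feats = replace(feats, b_bpm=rate, b_motion=corrupted)
        if prev is not None:
            flags = detect_motion(feats, prev, pth_motion)
            feats = replace(
                feats,
                p_depth_prev=prev.p_depth,
                m_above_sleep_level=flags.above_sleep_level,
                m_leave_zone=flags.leave_zone,
                m_boundary_zone=flags.boundary_zone,
            )
        prev = feats
        yield feats
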