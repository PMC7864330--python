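"""Room layouts, virtual monitoring zones, and the sensor's pixel grid.

A ceiling-mounted time-of-flight sensor looks straight down at the room and
returns a 512x424 grid of sensor-to-surface distances (cm).  Around each bed
three nested virtual fences are drawn on the floor plan:

* the **bed zone** — the bed rectangle itself; foreground pixels here that rise
  above the *sleep level* indicate a raised torso (sitting up);
* the **leave zone** — a strip around the bed where someone stands when getting
  in or out of bed;
* the **boundary zone** — an outer ring whose crossing means the person has
  left the bedside area entirely.

The sleep level sits ``D_offset`` centimetres above the bed surface, where
``D_offset`` is the thickness of a lying body plus a 2 cm margin, so a person
lying flat (even rolling over) stays below it while a sitting torso rises
above it.

Floor coordinates are in cm with the origin at the room corner nearest the
door; pixel (row 0, col 0) is the image top-left.  The mapping from floor plan
to pixel grid is orthographic: each pixel covers a small floor cell inside the
sensor's rectangular footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FRAME_WIDTH = 512
FRAME_HEIGHT = 424
FPS = 6

#: side names for axis-aligned rectangles
SIDES = ("x0", "x1", "y0", "y1")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in floor coordinates (cm)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centre(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def intersects(self, other: "Rect") -> bool:
        return not (
            other.x1 <= self.x0
            or self.x1 <= other.x0
            or other.y1 <= self.y0
            or self.y1 <= other.y0
        )

    def dilate(self, margins: dict[str, float] | float) -> "Rect":
        """Grow the rectangle outward; ``margins`` is per-side or uniform."""
        if isinstance(margins, (int, float)):
            margins = {s: float(margins) for s in SIDES}
        return Rect(
            self.x0 - margins.get("x0", 0.0),
            self.y0 - margins.get("y0", 0.0),
            self.x1 + margins.get("x1", 0.0),
            self.y1 + margins.get("y1", 0.0),
        )

    def clip_to(self, outer: "Rect") -> "Rect":
        return Rect(
            max(self.x0, outer.x0),
            max(self.y0, outer.y0),
            min(self.x1, outer.x1),
            min(self.y1, outer.y1),
        )

    @staticmethod
    def centred(cx: float, cy: float, w: float, h: float) -> "Rect":
        return Rect(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass(frozen=True)
class BedGeometry:
    """One bed: rectangle, surface height, its sensor, and exit side(s).

    ``exit_sides`` names the face(s) of the bed through which the subject can
    get in or out ('x0' is the face at ``rect.x0``, etc.).
    """

    rect: Rect
    surface_height_cm: float
    sensor_height_cm: float
    exit_sides: tuple[str, ...] = ("x0",)

    @property
    def exit_side(self) -> str:
        return self.exit_sides[0]

    def exit_face_centre(self, offset_cm: float = 0.0) -> tuple[float, float]:
        """Point at the middle of the primary exit face, ``offset_cm`` outward."""
        cx, cy = self.rect.centre
        s = self.exit_side
        if s == "x0":
            return (self.rect.x0 - offset_cm, cy)
        if s == "x1":
            return (self.rect.x1 + offset_cm, cy)
        if s == "y0":
            return (cx, self.rect.y0 - offset_cm)
        return (cx, self.rect.y1 + offset_cm)


@dataclass(frozen=True)
class RoomLayout:
    """Dimensioned room: extent, beds, entries, and per-bed sensor footprints."""

    preset: str
    room: Rect
    beds: tuple[BedGeometry, ...]
    door_cm: tuple[float, float]
    toilet_cm: tuple[float, float]
    #: one sensor footprint per bed; each sensor images only its footprint
    footprints: tuple[Rect, ...] = ()

    def __post_init__(self) -> None:
        for bed in self.beds:
            if not self.room.contains_rect(bed.rect):
                raise ValueError("bed rectangle outside room extent")
            if bed.sensor_height_cm <= bed.surface_height_cm + 100:
                raise ValueError("sensor must sit >100 cm above the bed surface")
        if len(self.beds) == 2 and self.beds[0].rect.intersects(self.beds[1].rect):
            raise ValueError("double-bed preset requires non-overlapping beds")
        if not self.footprints:
            object.__setattr__(self, "footprints", tuple(self.room for _ in self.beds))

    @property
    def n_beds(self) -> int:
        return len(self.beds)


# Bed dimensions: 196 x 90 cm in both settings.  Single setting: surface at
# 55 cm, sensor 270 cm above the floor.  Double setting: wooden beds with
# 38 cm surface, sensors at 230 cm, the two beds in diagonal corners with the
# remaining corners acting as room entry and toilet entry.
BED_LENGTH_CM = 196.0
BED_WIDTH_CM = 90.0


def make_layout(preset: str) -> RoomLayout:
    """Build the dimensioned single- or double-bed room layout.

    Parameters
    ----------
    preset:
        ``"single"`` — one 196x90 cm bed (surface 55 cm) against the far wall,
        sensor 270 cm above the floor, exit only on the bed's left (room-facing)
        side.  ``"double"`` — two 196x90 cm beds (surface 38 cm) in diagonal
        corners of a larger room, one sensor per bed at 230 cm, each sensor
        imaging its own half of the room.
    """
    if preset == "single":
        room = Rect(0, 0, 400, 300)
        bed = BedGeometry(
            rect=Rect(310, 104, 400, 300),
            surface_height_cm=55.0,
            sensor_height_cm=270.0,
            exit_sides=("x0",),
        )
        return RoomLayout(
            preset="single",
            room=room,
            beds=(bed,),
            door_cm=(25.0, 25.0),
            toilet_cm=(25.0, 275.0),
            footprints=(room,),
        )
    if preset == "double":
        room = Rect(0, 0, 600, 400)
        bed_a = BedGeometry(
            rect=Rect(0, 0, BED_WIDTH_CM, BED_LENGTH_CM),
            surface_height_cm=38.0,
            sensor_height_cm=230.0,
            exit_sides=("x1",),
        )
        bed_b = BedGeometry(
            rect=Rect(600 - BED_WIDTH_CM, 400 - BED_LENGTH_CM, 600, 400),
            surface_height_cm=38.0,
            sensor_height_cm=230.0,
            exit_sides=("x0",),
        )
        return RoomLayout(
            preset="double",
            room=room,
            beds=(bed_a, bed_b),
            door_cm=(575.0, 25.0),
            toilet_cm=(25.0, 375.0),
            # each unit renders only its half of the room
            footprints=(Rect(0, 0, 300, 400), Rect(300, 0, 600, 400)),
        )
    raise ValueError(f"unknown layout preset {preset!r}; expected 'single' or 'double'")


@dataclass(frozen=True)
class ZoneGeometry:
    """Nested virtual fences for one bed plus the reference distances.

    ``d_sleep = d_bed - d_offset`` is the sensor-to-sleep-level distance: a
    foreground pixel with depth below ``d_sleep`` lies *above* the sleep plane.
    """

    bed_zone: Rect
    leave_zone: Rect
    boundary_zone: Rect
    d_floor_cm: float
    d_bed_cm: float
    d_offset_cm: float

    def __post_init__(self) -> None:
        if not (self.d_sleep_cm < self.d_bed_cm < self.d_floor_cm):
            raise ValueError("require D_sleep < D_bed < D_floor")
        if not self.leave_zone.contains_rect(self.bed_zone) or self.leave_zone == self.bed_zone:
            raise ValueError("leave zone must strictly contain the bed rectangle")
        if not self.boundary_zone.contains_rect(self.leave_zone):
            raise ValueError("boundary zone must contain the leave zone")

    @property
    def d_sleep_cm(self) -> float:
        return self.d_bed_cm - self.d_offset_cm


#: default lying-body thickness used for D_offset (cm); + 2 cm margin
DEFAULT_LYING_THICKNESS_CM = 25.0
SLEEP_LEVEL_MARGIN_CM = 2.0
#: leave-zone strip width on the exit side and ring widths (cm)
LEAVE_MARGIN_EXIT_CM = 50.0
LEAVE_MARGIN_OTHER_CM = 50.0
BOUNDARY_MARGIN_CM = 50.0


def derive_zones(
    bed: BedGeometry,
    footprint: Rect,
    lying_thickness_cm: float = DEFAULT_LYING_THICKNESS_CM,
    leave_margin_exit_cm: float = LEAVE_MARGIN_EXIT_CM,
    leave_margin_other_cm: float = LEAVE_MARGIN_OTHER_CM,
    boundary_margin_cm: float = BOUNDARY_MARGIN_CM,
) -> ZoneGeometry:
    """Derive the three nested zones and reference distances for one bed.

    The bed zone is the bed rectangle; the leave zone dilates it by
    ``leave_margin_exit_cm`` on the exit side(s) and ``leave_margin_other_cm``
    elsewhere; the boundary zone adds a further ``boundary_margin_cm`` ring.
    Both outer zones are clipped to the sensor footprint, so in a double room
    the two beds' fences never overlap.
    """
    margins = {
        s: (leave_margin_exit_cm if s in bed.exit_sides else leave_margin_other_cm)
        for s in SIDES
    }
    leave = bed.rect.dilate(margins).clip_to(footprint)
    boundary = leave.dilate(boundary_margin_cm).clip_to(footprint)
    return ZoneGeometry(
        bed_zone=bed.rect,
        leave_zone=leave,
        boundary_zone=boundary,
        d_floor_cm=bed.sensor_height_cm,
        d_bed_cm=bed.sensor_height_cm - bed.surface_height_cm,
        d_offset_cm=lying_thickness_cm + SLEEP_LEVEL_MARGIN_CM,
    )


@dataclass
class SensorView:
    """Orthographic mapping between a sensor footprint and the pixel grid."""

    footprint: Rect
    sensor_height_cm: float
    width: int = FRAME_WIDTH
    height: int = FRAME_HEIGHT
    _col_x: np.ndarray = field(init=False, repr=False)
    _row_y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fx, fy = self.footprint, self.footprint
        self._col_x = fx.x0 + (np.arange(self.width) + 0.5) * fx.width / self.width
        self._row_y = fy.y0 + (np.arange(self.height) + 0.5) * fy.height / self.height

    @property
    def col_x_cm(self) -> np.ndarray:
        """x coordinate (cm) of each pixel column centre."""
        return self._col_x

    @property
    def row_y_cm(self) -> np.ndarray:
        """y coordinate (cm) of each pixel row centre."""
        return self._row_y

    @property
    def pixel_area_cm2(self) -> float:
        return (self.footprint.width / self.width) * (self.footprint.height / self.height)

    def rect_mask(self, rect: Rect) -> np.ndarray:
        """Boolean (height, width) mask of pixels whose centre lies in ``rect``."""
        in_x = (self._col_x >= rect.x0) & (self._col_x < rect.x1)
        in_y = (self._row_y >= rect.y0) & (self._row_y < rect.y1)
        return in_y[:, None] & in_x[None, :]

    def rect_slices(self, rect: Rect) -> tuple[slice, slice]:
        """(row, col) slices covering pixels whose centre lies in ``rect``."""
        c0, c1 = np.searchsorted(self._col_x, [rect.x0, rect.x1])
        r0, r1 = np.searchsorted(self._row_y, [rect.y0, rect.y1])
        return slice(int(r0), int(r1)), slice(int(c0), int(c1))


@dataclass(frozen=True)
class ZoneMasks:
    """Precomputed pixel masks for the three zone extents of one bed.

    The three extents are disjoint: ``leave_ring`` excludes the bed rectangle
    and ``boundary_ring`` excludes the leave zone, so each foreground pixel is
    counted in at most one of P_bed_zone / P_leave_zone / P_boundary_zone and
    the identity P_depth = sum of the three holds by construction.
    """

    bed: np.ndarray
    leave_ring: np.ndarray
    boundary_ring: np.ndarray

    @staticmethod
    def from_zones(view: SensorView, zones: ZoneGeometry) -> "ZoneMasks":
        bed = view.rect_mask(zones.bed_zone)
        leave = view.rect_mask(zones.leave_zone)
        boundary = view.rect_mask(zones.boundary_zone)
        return ZoneMasks(bed=bed, leave_ring=leave & ~bed, boundary_ring=boundary & ~leave)


def sensor_view(layout: RoomLayout, bed_index: int = 0) -> SensorView:
    """The pixel-grid mapping of the eNightLog unit watching ``bed_index``."""
    return SensorView(
        footprint=layout.footprints[bed_index],
        sensor_height_cm=layout.beds[bed_index].sensor_height_cm,
    )


def zones_for(layout: RoomLayout, bed_index: int = 0, **kwargs) -> ZoneGeometry:
    """Shorthand: derive the zone geometry of one bed of a layout."""
    return derive_zones(layout.beds[bed_index], layout.footprints[bed_index], **kwargs)
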