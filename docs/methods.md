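# Methods

This note documents the models behind `enightlog`: what is simulated, how the
detection chain works, which parameters matter, and where the design was
genuinely open.

## Scene and sensing model

The monitored scene is a room in floor coordinates (cm, origin at the corner
nearest the door, pixel (0,0) at the image top-left).  Two presets are built
in:

* **single** — a 400×300 cm room with one 196×90 cm bed (surface 55 cm)
  against the far wall and the sensor 270 cm above the floor.  The subject
  can enter and exit the bed only on its room-facing side.
* **double** — a 600×400 cm room with two 196×90 cm beds (surface 38 cm) in
  diagonal corners, one sensor per bed at 230 cm.  Each sensor images only
  its half of the room, mirroring two independent monitoring units whose
  virtual fences never overlap; the free corners act as room entry and toilet
  entry.

The depth camera is modelled orthographically: each of the 512×424 pixels
covers a small floor cell of the sensor footprint and reads the distance to
the tallest surface under it (nearest surface wins; occlusion is therefore
exact by construction).  This drops the perspective distortion of a real
time-of-flight camera.  For a ceiling-mounted sensor looking straight down at
a single bed the distortion mainly shifts zone boundaries by a few
centimetres at the image periphery, which the configurable zone margins
absorb; calibrating a true projective mapping is out of scope.

Actors are axis-aligned cuboids: standing 44×44 cm footprint at body height
(default 175 cm), sitting 50×50 cm at bed surface + 85 cm, lying 50×170 cm at
bed surface + 25 cm, oriented along the bed's long axis.  Only zone pixel
counts reach the classifier, so an articulated body adds nothing.  Sensor
noise is zero-mean Gaussian per pixel (default sd 1 cm) with depths clamped
to [0, D_floor].

The ultrawideband radar is reduced to its used output: a per-second
breaths-per-minute value for the bed's footprint (bed rectangle dilated
35 cm).  A resting (lying/sitting, still) occupant yields a rate around a
per-subject nominal (default 14 min⁻¹, sd 0.6); gross motion in the footprint
marks the second motion-corrupted (presence confirmed, no valid rate); an
empty footprint yields 0.

## Zones and reference distances

The bed zone is the bed rectangle.  The leave zone dilates it by 50 cm
(configurable per side; the spec of a real room may restrict it to the exit
side) and the boundary zone adds a further 50 cm ring, both clipped to the
sensor footprint.  For counting, the three extents are disjoint rings, so the
identity P_depth = P_bed_zone + P_leave_zone + P_boundary_zone holds exactly.

D_floor equals the sensor mount height; D_bed = D_floor − bed surface height;
D_offset = lying-body thickness (25 cm) + 2 cm margin; the sleep level is
D_sleep = D_bed − D_offset.  A lying body therefore sits 2 cm *below* the
sleep plane, and a raised torso about 58 cm above it.

## Scripted scenarios

Sc1–Sc9 follow the bed-time protocols a hostel caregiver would stage: plain
exit, rolling over, toilet trip (the full sequence twice → two exits),
drinking, device use, sneezing, caregiver helping, visitor checking,
coughing.  Step durations are not part of the protocol; defaults of 2–10 s
per action with seeded ±20 % jitter are used, giving 40–100 s trials.  The
double-bed variants of Sc3/Sc7/Sc8 route the toilet trip through the other
bed's zones and have the caregiver/visitor check both beds before returning
to the door.  Ground truth logs an exit when the subject's centre leaves the
leave zone after at least 5 s inside it; every trial starts with 5.5 s of
empty-room frames for background acquisition.

## Detection chain and parameters

| parameter | default | unit | why |
|---|---|---|---|
| frame rate | 6 | fps | silhouette-video rate of the monitoring system |
| foreground threshold | 5 | cm | > 3σ of default noise, ≪ any body thickness |
| background motion tolerance | 20 | cm | noise ranges stay < 10 cm over the 5 s window; a person changes depth by ≥ 80 cm |
| pTh_above_sleep_level | 800 | px | lying-body noise leakage above the sleep plane peaks near 350 px at sd 1 cm; a sitting torso covers ~2700 px |
| pTh_leave_zone, pTh_boundary | 200 | px | a standing body covers ~2700 px in a ring; ring noise is negligible (foreground already thresholded) |
| pTh_motion | 50 | px | flags inter-frame count changes clearly above jitter |
| debounce | 3 | frames | 0.5 s: single-frame spikes never switch state |
| arming time | 12 | frames | 2 s of lying-with-valid-rate before monitoring arms |
| match window | 10 | s | observer-button vs. system timestamp tolerance |
| CBD pattern window | 30 | s | mat-release to fence-clear timeout, refreshed while the subject sits at the edge |

The pixel thresholds are calibrated to this simulator's pixel density
(~1.8 px/cm² in the single room); a deployment would re-derive them from its
own geometry, which is why all of them live in the YAML config.

The classifier's branch structure is an explicit reconstruction — the
published system names its states, thresholds and alarm levels but not the
branching order.  Ordered tests per frame, first match wins: (1) a raised
torso in the bed zone means `sit`; (2) ring activity while the radar still
confirms the subject on the bed means `others` (visitor), without presence it
means `exiting_bed`; (3) from `exiting_bed`, empty zones with no radar
presence mean `leave`; (4) from `others`, everything vanishing means
`both_leave`, the zones emptying with the subject still present falls back to
`sleep_locked`; (5) from `leave`/`both_leave`, ring activity or returning
presence re-enters the machine, so the toilet scenario re-arms and yields a
second event.  B_bpm is used for presence only, never as a posture feature.
Alarms are suppressed until the classifier first arms.  How to treat a
visitor arriving while the subject is already sitting is unspecified in the
source system; here the leave-zone test wins, which classifies that corner
case as an exit in progress (a conservative, alarm-raising choice).

## Baseline

The CBD baseline senses presence, not beam interruption, to match its
described on/off semantics.  The mat is a 60×120 cm rectangle flush with the
exit edge; sitting on the bed side presses mat and fence simultaneously.  A
standing person leaning within 15 cm of the mat can press it (flag, default
on) — with a subject lying on the mat this rarely matters, and the synthetic
baseline consequently shows far better specificity than its real-world
counterpart: the mechanisms behind real mat false alarms (mat displacement
after rolls, partial coverage) are modelled only as optional flags, not
asserted.  In the double room a walker from the inner bed pulses the outer
bed's fence — the structural false-alarm source that motivates keeping the
baseline single-bed only.

## Evaluation

Each scenario move contributes exactly one positive and one negative
opportunity.  A detection within the match window of the true exit scores the
move's TP (each detection matches at most one exit); any unmatched detection
inside the move's window scores its single FP.  This makes TP+FN and TN+FP
each equal the scheduled move total — 10 moves per subject per round
(9 scenarios + the second Sc3 exit), hence 900 for 30 subjects × 3 rounds,
and 300 per pair per 3 rounds of the 45 unordered scenario combinations in
the double room (4500 for 15 pairs).  Metrics are percentages rounded half-up
to one decimal; a zero-denominator metric is reported as undefined (N/A),
never 0.

Desk-scale experiments (the defaults of `scripts/acceptance.py`) use 2
subjects × 3 rounds single-bed (120 moves per system) and 1 pair × 1 round
double-bed (100 moves), noiseless rendering; a full-protocol simulation is a
straight scale-up of the same code.

## What the simulator does and does not show

Passing end-to-end tests show the chain is *internally consistent*: scripted
exits produce the alarm sequence none → yellow → red and exactly the
ground-truth number of events, visitors produce `others` and no alarms, and
the bookkeeping balances.  They do not show field performance: real people
are not cuboids, quilts and furniture deform the depth field, real radar
drops out, and real caregivers behave less predictably than scripts.  In the
double room the simulator does reproduce one real failure mode — a visitor
entering a bed's zones while that bed's occupant is away is indistinguishable
from the occupant returning and leaving, producing occasional false exits and
a double-bed specificity a few points below 100 %.

## Numerical and degenerate-input choices

Background acquisition requires ≥ 30 frames and returns the *first* frame,
failing loudly on motion.  Foreground pixels keep their original depth so the
sleep-level test stays a depth comparison; subtraction is idempotent.  The
silhouette maps the closest foreground depth to 255 and the farthest to 1
(a constant-depth blob maps to 255; an empty foreground yields an all-zero
image), so output images depend only on the normalised bins, not raw depths.
Zone masks assign a pixel by its centre; degenerate rectangles are rejected
at construction.  All randomness flows from explicit integer seeds (kept
below 2³¹), and identical seeds reproduce bit-identical frames, radar series
and logs.

## Known limitations

* Orthographic rendering and cuboid bodies; no quilts, furniture, walking
  aids, or articulated posture transitions.
* The classifier's branch order is a reconstruction (see above); the real
  system's internal-only states are not modelled beyond the six named ones.
* The baseline's false-alarm mechanisms are flags, not physics; its simulated
  specificity should not be compared against field numbers.
* One subject per sensor; multi-subject tracking under a single sensor, fall
  detection and sleep-quality scoring are out of scope.
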