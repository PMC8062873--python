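# Methods

This note documents the models, conventions and numerical choices behind
locokit, and what its synthetic generators do and do not emulate.

## Input model and conventions

The universal input is a pose track: per-frame (x, y) coordinates and a
detection likelihood for named landmarks, in the three-header CSV dialect
(scorer / bodyparts / coords) common to markerless trackers. Coordinates use
image conventions (y increases downward); every downstream geometric
quantity (interior angles, bisector intersections, distances) is invariant
to orientation, so no axis flip is ever applied.

Timestamps from a companion file take precedence over the nominal frame
rate (real cameras drop and jitter frames); absent a file, t_i = i / fps.
Calibration recovers a single isotropic cm-per-pixel scale as the
zero-intercept least-squares fit of known inter-marker distances against
median observed pixel distances over all marker pairs; lens distortion and
perspective are assumed negligible, as is standard for a camera mounted
square to the arena or corridor.

## Quality filtering

Filtering only ever masks points; masked frames are never interpolated at
this stage (downstream operations decide their own gap policy).

* likelihood < 0.8 → point masked (all modes);
* outside the arena bounds (when configured) → point masked;
* instantaneous speed above the cap → the **later** frame of the violating
  adjacent-frame pair is masked. Caps: 334 cm/s for the body center (the
  maximum locomotor speed recorded in mice), 400 cm/s for paws and joints
  (a 20% margin for individual body parts). Only strictly adjacent frame
  pairs with both frames still valid are tested, which makes the filter
  idempotent and keeps a single bad frame from contaminating its neighbors.
* in joints mode, two adjacent chain landmarks more than 2.3 cm apart (mean
  mouse tibia length + 30%) invalidate the **whole frame**. This anatomical
  rule is evaluated on likelihood-valid points *before* speed masking, so a
  grossly displaced joint always voids its frame rather than being silently
  removed by the speed cap first.

Stimulation epochs are read from the likelihood channel of the indicator-LED
landmark (the LED is only detectable while lit): on-runs at likelihood
≥ 0.8, gaps < 0.5 s closed, runs < 1 s dropped, offset extended one frame
period past the last lit frame so a k-frame train has duration k/fps. How a
given tracker actually binarizes an LED is tool-dependent, so an explicit
epochs file (onset_s, offset_s, power_pct) is supported as the bypass.

## Open-field analysis

Speed is the finite difference of consecutive body-center positions,
assigned to the later timestamp; it is masked when either endpoint frame is
masked. Downsampling to 20 Hz uses linear interpolation of valid samples on
a uniform grid; grid points falling in masked gaps longer than one native
frame are masked rather than bridged. Peri-stimulus profiles snap each train
onset to the nearest grid sample (one-sample maximum alignment error) and
average across trains; SEM is computed over trains (ddof = 1), matching the
usual "n stimulations per animal" reporting unit.

The laser-power/speed relationship normalizes power and speed to each
animal's maxima (×100), pools trials, bins them by normalized power in
(0, 100] with 10-point bins, and fits the binned means with the 3-parameter
logistic y = a / (1 + exp(−(x − x₀)/b)) by Levenberg–Marquardt least squares
(initialization a = max y, x₀ = median x, b = range(x)/4). For nonlinear
fits R is reported as sqrt(max(0, 1 − SS_res/SS_tot)), the convention of
common curve-fitting software; 95% prediction intervals use the first-order
delta method. Only the 3-parameter family is implemented; a 4-parameter
(nonzero floor) variant was considered and rejected because the assays
normalize the floor to zero by construction.

## Corner turns

A candidate is a maximal run of valid positions inside the 20-cm corner ROI;
masked gaps of ≤ 3 frames are bridged, longer gaps split the run (preventing
spurious "turns" spanning tracking dropouts). The turning point is the
unique intersection of the piecewise-linear trajectory with the corner's
bisector ray (vertex → arena interior, length = arena diagonal),
intersections computed segment by segment with inclusive endpoints and
shared-vertex duplicates counted once. Zero or multiple crossings, or
endpoints closer than 5 cm (inclusive boundary) to the turning point, reject
the candidate — rejections are returned as values with reason codes, never
exceptions.

Distance to the turning point is Euclidean (not path length), signed by time
relative to the crossing; a point exactly at the crossing ties to the
positive side. Speeds attached to trajectory points reuse the later-frame
convention. Bins are 1 cm wide over [−20, 20). Turn speed averages the four
bins covering [−2, 2); entry (exit) speed averages the four most distal
*occupied* bins whose near edge is ≥ 7 cm from the turning point — 5 cm from
the boundary of the 2-cm turning zone, the literal reading of "away from the
turning zone". Both choices the text leaves open are configurable:
`entry_exit_min_distance` can be set to 5 for the ≥ 5 cm-from-the-point
reading, and distality counts occupied bins. Any summary with fewer than
four occupied eligible bins rejects the whole turn.

The four scaling regressions (entry vs entry − turn; exit vs exit − turn;
entry vs turn; turn vs angle) are ordinary least squares; R is the signed
Pearson correlation and P the two-sided slope test with n − 2 df.

## Gait and kinematics

Paw speeds are smoothed with a 5-frame centered moving average (masked
frames excluded from each window; edges use available samples). Touchdown /
lift-off are the downward / upward crossings of 15 cm/s, with sub-frame
timing by linear interpolation — at 300 fps this stabilizes duration metrics
at negligible cost. No hysteresis is applied at the threshold (a
configurable debounce, default off, exists for noisy user data); alternation
is enforced by dropping same-type repeats, keeping the first. Stride length
is the same paw's planar displacement between consecutive touchdowns
(configurable in principle to a body-displacement convention; the same-paw
reading is the field's default). Stance + swing = cycle exactly, by
construction from shared event times.

Gait diagrams map each limb's complete stance intervals (both boundary
events present) onto the reference cycle between consecutive left-hindlimb
touchdowns; start phases are clipped at 0 and end phases may exceed 1 for
stances outlasting the cycle.

Joint angles are interior angles at each inner chain landmark between its
two chain neighbors, in (0, 180]; no signed/reflex convention is used. (A
figure-caption description of "two proximal joints" conflicts with the
chain reading; the adjacent-neighbor convention is implemented.) MTP
stance/swing detection uses a 9 cm/s threshold and requires ≥ 8 consecutive
frames above threshold to accept a lift-off. Cycle normalization resamples
each touchdown-to-touchdown angle trace at 100 phase-bin centers by linear
interpolation, skipping cycles with > 20% masked frames; amplitude is
per-cycle max − min averaged over cycles (robust to phase jitter), with the
amplitude-of-mean-profile variant available as an option.

## Synthetic generators

The generators' defaults are the study conditions: a 40 × 40 cm arena at
30 fps for 15 min with ten 10 s stimulation trains every 80 s (open field),
and 300 fps corridor recordings with four calibration markers 5 cm apart.
Tracks are emitted in pixel units (10–12 px/cm) with in-frame calibration
landmarks so ingestion, calibration and filtering are exercised, with
Gaussian tracking jitter of 0.02 cm (open field) / 0.005 cm (corridor) —
about 0.2 px, typical sub-pixel tracker noise — plus sparse likelihood
dropouts and gross coordinate outliers. Outlier displacements are drawn
large enough (15–25 cm) that their implied frame speed always violates the
physiological cap: every injected artifact is removable by the quality
filters, by contract.

**Open field.** A kinematic wall-following agent runs a loop whose corner
pivots lie exactly on the arena diagonals (7 cm inset, jittered along the
diagonal), so each programmed turning point, crossing time and turn angle is
known exactly; legs are straight, so the measured first/turning-point/last
angle equals the angle of the realized pivot triangle. Commanded speed is
the baseline 8 cm/s off-train and a logistic function of laser power
(a = 40 cm/s, x₀ = 50%, b = 15%) during trains. Approaching a pivot the
agent decelerates linearly from 7 cm out to its turn speed, holds it within
2.5 cm, and re-accelerates symmetrically; the turn speed follows the
programmed braking law turn = α·entry + β + ε (defaults α = 0.3, β = 0,
σ_ε = 0.5 cm/s), and the pivot's diagonal offset is coupled to turn speed,
giving the angle–speed relationship. These linear-with-noise laws are a
design choice so the scaling regressions have known ground truth — they are
not a claim about mouse behavior. The indicator-LED landmark has high
likelihood exactly while a train is on. Trajectories are noiseless polylines
before the tracking-noise stage; agent dynamics are kinematic, with no
physics, no wall compliance, and none of the pauses, rearing or grooming of
real mice — so passing tests demonstrates correctness of the measurement
pipeline, not robustness to every real-world behavior.

**Corridor gait.** Each paw is stationary during stance and advances one
stride per cycle along a half-sine speed profile, with per-limb phase
offsets (trot defaults: 0, 0.5, 0.5, 0 for LF, RF, LH, RH). The programmed
duty factor is *threshold-referenced*: the half-sine is stretched so that
its crossings of the event-detection threshold fall exactly at the
programmed stance/swing boundaries, making the ground-truth event times
identical to what an ideal crossing detector measures. (With a naive
profile, threshold crossings lag kinematic events by ~2 frames and no
detector could recover the programmed duty factor to within a frame.) Peak
swing speed is solved from stride length, swing duration and threshold by
bisection on the fast-swing branch of the (U-shaped) stride–peak relation.
A zero stride degenerates to standing: static paws, no events.

**Hindlimb kinematics.** The MTP follows the same foothold model (9 cm/s
threshold reference, horizontal path); interior joint angles are programmed
sinusoids of cycle phase (defaults: hip 25°, knee 40°, ankle 35°, MTP 30°
peak-to-peak around physiological means), and the chain is constructed
distal-to-proximal from the MTP with fixed segment lengths (all < 2.3 cm),
alternating rotation signs for a leg-like zigzag. Both MTP events and
per-frame joint angles are therefore exact ground truth; the cost is that
the iliac crest, being derived, bobs more than a real pelvis marker.

## Numerical notes and known limitations

* Finite-difference speeds sit on the later-frame grid, half a frame after
  the interval they measure; event times inherit this ~dt/2 offset. Cycle,
  stance and swing durations are differences of event times, so the offset
  cancels there.
* Tracking noise adds a positive, speed-dependent bias to measured speed
  (≈ σ²·fps/v for v ≫ σ·fps), which slightly inflates low turn speeds and
  attenuates the recovered braking slope by a few percent at the default
  noise level; commanded-speed changes that land inside a turn's measurement
  window (rare: train toggles every 40 s) mislabel single turns and add
  scatter. Recovery tests budget for both.
* Peri-stimulus alignment snaps onsets to the 20 Hz grid (≤ 25 ms error).
* Sigmoid fitting can in principle fail to converge on pathological data;
  the result carries a `converged` flag and residual report instead of
  raising.
* The turn pipeline assumes a convex quadrilateral arena; the bisector is
  the ray bisecting the two adjacent walls.
* Masked data are handled by exclusion throughout; no imputation anywhere.
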