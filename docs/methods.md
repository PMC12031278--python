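# Methods

## Problem and model

A body-worn IMU records accelerometer **a**, gyroscope **ω** and
magnetometer **m** in its own case frame. During alpine skiing the case
frame is arbitrary (a phone in a pocket, a sensor strapped at a random
angle), so the lateral "turning" signal is smeared across all three raw
axes. The pipeline recovers a placement- and orientation-invariant view
in three stages.

### 1. Attitude from a quaternion complementary filter

The sensor-to-world rotation is tracked as a scalar-first unit
quaternion q(t) (world frame: Y up, X/Z horizontal). Per sample at rate
f_s (default 50 Hz, dt = 1/f_s):

1. **Gyro propagation.** q ← q ∗ q(dt‖ω‖, ω/‖ω‖), the axis-angle
   increment of the current rate sample (identity for ‖ω‖ → 0).
2. **Tilt correction.** Rotate the raw accelerometer sample into the
   world frame, a_w = q a q⁻¹. Its normalized direction v should be
   world up ŷ; the misalignment has angle Φ = arccos(v_y) and axis
   n = v × ŷ = (−v_z, 0, v_x). The estimate is pre-multiplied by a
   rotation of (1 − α_c)·Φ about n̂: a complementary blend that trusts
   the gyro at high frequency and the accelerometer's gravity direction
   at low frequency.
3. **Yaw correction** (optional, magnetometer). The heading of the
   rotated field, θ = atan2(m′_x, m′_z), is compared against the
   heading θ_ref of the reference reading taken at the start of the
   recording (rotated by the initial attitude). The estimate is
   pre-multiplied by a rotation of (1 − α_y)·(θ_ref − θ) about world Y.
   With the heading convention above, a +ψ pre-rotation about Y shifts
   θ by +ψ, so this sign is the convergent one: the heading error
   decays geometrically as α_y per step. Steps whose rotated field is
   (near-)vertical are skipped — yaw is unobservable there.
4. q is renormalized every step (floating-point drift control), and the
   raw acceleration rotated by the final attitude is emitted.

With α_c = α_y = 1 the filter is exactly gyro dead-reckoning (asserted
by a test). Initialization: the starting attitude is the tilt-only
rotation mapping the mean accelerometer vector of the first
`init_window_s` seconds (default 1 s; the simulator prepends a 1-s
static lead-in) onto ŷ — its yaw is zero by construction — and the
magnetometer reference is the mean field over the same window.

**Gains.** Defaults α_c = α_y = 0.98 at 50 Hz give a correction time
constant dt/(1 − α) = 1 s: fast enough to absorb MEMS-grade gyro bias
(0.01 rad/s per axis leaves a ≲1° steady tilt error, the drift bound
the tests verify), slow enough that turn dynamics do not destroy the
attitude. Tilt correction is applied unconditionally every sample (no
accelerometer-magnitude gating); the gain itself suppresses
dynamic-acceleration corruption.

**Sign convention.** A resting accelerometer outputs the specific force
+g along its up direction, so a converged static filter emits world
acceleration (0, +g, 0).

### 2. Side-motion identification (global wavelet spectrum)

After fusion, gravity sits on world Y ("up"); turning and fore–aft
motion share X and Z. Turning is strongly periodic at the turn cadence,
so each horizontal axis is scored by the *global wavelet spectrum* —
time-averaged CWT power per scale, complex Morlet ω₀ = 6, logarithmic
scales at 8 voices per octave over periods 0.5–16 s (covering
short-radius to long-radius cadences). The axis with the higher peak is
"side", the other "forward"; exact ties break toward X with a warning.
The decision is made once per run (not per 12-s segment) so the axis
cannot flip mid-recording, and it is invariant to common rescaling of
both candidates. Cone-of-influence correction and significance testing
are deliberately omitted — only the argmax comparison matters.

### 3. Turn detection and evaluation

The side series is filtered with a second-order Butterworth at 2 Hz
applied forward–backward (zero phase, so extremum timestamps are not
lag-shifted; note zero-phase filtering squares the magnitude response —
a 5 Hz sine emerges at |H(5)|² ≈ 0.022 with the digital design, ≈ 0.025
by the analog closed form 1/(1+(f/f_c)⁴)). Turning points are the peaks
and valleys of the filtered series: each extremum is one turn, the zero
crossing between two extrema the switch. Extrema must be
`min_separation` (default 0.6 s; use 0.4 s for 1 Hz short-radius
cadences) apart — enforced across peak/valley types, keeping the more
prominent of two conflicting extrema, which also suppresses shallow
filter-edge artifacts — and must have prominence ≥ 10 % of the signal
range, making detection invariant to positive rescaling. Peaks and
valleys strictly alternate in the output.

Evaluation follows the per-segment design: recordings are cut into
consecutive 12-s segments, counts compared by RMSE, MAE and the
population standard deviation of the turn detection rate
(detected/actual). Baseline detectors (raw accY, raw gyrX, roll angle
atan2(a_y, a_z) unwrapped, and a constant five turns per segment) share
the same filter and peak rules. Correlation comparisons between side
series use a 4 Hz low-pass and |r|, tolerating the left/right sign
ambiguity of the heading reference.

## The simulator

`skiturn.simulate` generates the body-frame inertial signature of
linked turns, not a slope-descent trajectory: world specific force
g·ŷ + A_s sin(2πf t)·ŝ + A_f sin(4πf t)·f̂, body roll
φ(t) = φ₀ sin(2πf t) about the forward axis co-phased with the lateral
force, and a flexion-driven pitch θ₀ sin(4πf t) about the side axis at
twice the cadence (each turn cycle contains two flexion/speed phases).
Angular velocity is derived in closed form from the rotation
composition, then everything is expressed in the sensor frame through a
fixed random mounting rotation; gyro bias, white sensor noise and a
constant world magnetic field with a dominant horizontal component are
added. Defaults (0.5 Hz cadence, ±20° roll, 2 m/s² lateral and
0.5 m/s² fore–aft force, ±8.6° pitch, σ_acc = 0.4 m/s² → SNR 5,
σ_gyr = 0.02 rad/s, bias 0.01 rad/s/axis) describe a recreational
short/medium-radius descent. The doubled-frequency pitch/fore–aft pair
matters for realism: with a single roll frequency the raw gyro-X
channel would be a perfectly scaled copy of the turn waveform under
almost any mounting, which real limb dynamics do not permit.

What the simulator does **not** emulate: terrain and snow interaction,
per-limb articulated dynamics, sensor-quality differences,
magnetometer hard/soft-iron distortion, clock drift between devices.
Passing tests therefore demonstrate orientation/placement invariance
and detector behavior under realistic noise, bias and mounting
conditions — not performance on field data.

## Verification studies and their design choices

- **Static convergence** (100 random mountings, σ_acc = 0.05 m/s²,
  bias 0.01 rad/s/axis): corrected up error < 2° after 5 s for every
  mounting; gyro-only 30-s error compared on the *median* (≈ 25–28°) —
  a bias nearly parallel to gravity yields pure yaw drift and almost no
  up error, so a per-mounting bound cannot hold.
- **Orientation invariance** (one motion, 20 mountings, per-sensor
  noise): pairwise |r| of 4 Hz-filtered side series ≥ 0.95 and equal
  turn counts during the motion (the static lead-in is rest, not
  activity). The motion is laterally dominated (no fore–aft force):
  how horizontal acceleration splits between world X and Z depends on
  the mounting's heading relative to the magnetic reference — the
  known, unresolved heading-redistribution problem, which is out of
  scope here — so a competing forward component would probe that
  excluded effect rather than mounting invariance.
- **Turn recovery** (200 runs, cadence 0.25–1 Hz, random mountings):
  ≥ 95 % of 12-s segments within ±1 turn (measured ≈ 99 %).
- **Baseline contrast** (40 runs, random mountings): side-motion RMSE
  ≈ 0.2 turns versus ≈ 2–10 for accY/gyrX/roll and 6.8 for the
  constant-5 floor.
- **Axis selection** (200 runs): the expected label is geometric — the
  filter-frame axis carrying the larger projection of the true lateral
  direction, via the residual estimated-vs-true rotation. Headings near
  45° make the label genuinely ambiguous; accuracy ≥ 95 % (measured
  ≈ 99 %).

Problem sizes (60-s runs, 50 Hz, the trial counts above) are the
package's chosen study scale; every study is deterministic given its
seed.

## Numerical choices and degenerate inputs

- Quaternion comparisons always go through rotations (q ≡ −q); the
  rotation distance uses the chordal form 4·arcsin(d/2), accurate near
  identity where arccos of the dot product loses half the precision.
- Resampling is linear interpolation onto a uniform grid starting at
  the first timestamp common to all streams — defensible because the
  50 Hz target sits far below source rates and downstream filtering is
  aggressive. Duplicate timestamps are averaged; rows with non-finite
  time/inertial values are dropped and counted.
- Zero gyro rate → identity increment; zero accelerometer sample →
  tilt correction skipped; vertical rotated field → yaw step skipped
  and counted; constant signals → degenerate wavelet spectrum, and axis
  selection errors out only when both candidates are degenerate.
- Segmentation discards the trailing remainder; segments are
  consecutive, disjoint, of exactly round(12·f_s) samples.

## Known limitations

- **Tilt-correction phase lag.** The lateral force is co-phased with
  roll, so the tilt correction is periodically dragged toward the
  dynamic specific-force direction, leaving a steady ~3° attitude
  wobble that phase-shifts the recovered side series by ~15° at the
  default gain. Turn counts and cross-mounting correlations are
  unaffected (all mountings share the lag), but correlation against
  the *true* lateral waveform saturates near |r| ≈ 0.93–0.97 rather
  than 1.
- **Heading split between horizontal axes.** When the travel direction
  sits near 45° to the magnetic reference axes, lateral power divides
  between world X and Z; the winner-takes-all axis selection then
  recovers an attenuated side series. Redistributing by heading is
  explicitly left out.
- The magnetometer is assumed calibrated; only its direction is used.
- The filter is offline here (whole-recording convenience API), but the
  state update is strictly per-sample and streaming-capable.
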