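# Methods

This note documents the models behind `stimloop`, the parameters that
matter, the numerical choices, and what the synthetic generators do and do
not emulate.

## The virtual rig

The package is organized around a closed loop: camera frames → keypoint
pose → trigger rule → pixel→voltage lookup → galvanometer/laser actuation →
realized laser spot. Hardware is replaced by explicit models so every stage
is testable.

### Optics forward model

`OpticsModel` maps a commanded voltage pair to a laser-spot pixel as
`pixel = linear(voltage) + D(pixel_lin) + ε`, where the linear part is a
per-axis gain (default 0.01 V/px over a 1100 × 1100 px platform), `D` is a
smooth 2-D polynomial distortion (default degree 2) expressed in pixel
coordinates normalized to [-1, 1], and `ε` is isotropic Gaussian
spot-observation noise (default sd 0.8 px, emulating sub-pixel centroid
noise in spot detection). Distortion magnitude is validated to stay below
5% of the platform width, which keeps the forward map injective on the
platform; `make_distorted_optics` draws random distortion coefficients and
rescales them to a requested peak magnitude (default 20 px). Voltages
outside the physical range are refused, mirroring driver limits.

### Gait generator

`simulate_gait` advances the body (tail base) at a constant speed along a
lane, bouncing off the arena margins, while each paw alternates stance
(planted at a fixed pixel) and swing (linear travel to the next plant).
Stance and swing durations are drawn per cycle from normal distributions
(defaults 350 ± 44 ms and 100 ± 1 ms — the locomotion regime in which hind
paws dwell long enough to be targeted through an ~87 ms loop delay) and the
left/right hind paws are half a cycle out of phase.

Two quantization choices make duration recovery exact rather than
frame-biased: sampled durations are converted to whole frames by *unbiased
stochastic rounding* (floor plus a Bernoulli on the fractional part), and a
swing lands on its new plant position at its final frame. With frame labels
assigned from each frame's incoming displacement, run lengths then equal the
generated frame counts exactly, so run-length × frame-interval is an
unbiased estimator of the configured stance/swing means. Only the timing
statistics are contractual; the linear swing trajectory is a convenience.

Speed presets (`stationary`, `low`, `medium`, `high`) pair body speeds of
0/70/170/300 px/s with stance means of ∞/800/350/150 ms, reproducing the
qualitative decline of the static-hind-paw-frame fraction with body speed
(1.0 → ~0.89 → ~0.78 → ~0.60). The stance-versus-speed pairing is a modeling
choice (slower walking means longer stances), not a measured relation.

### Latency model

Processing (84 ± 12 ms) and actuation (3.3 ± 0.5 ms) delays are sampled
independently per stimulus from normals truncated at zero (rejection
sampling; the truncation is numerically irrelevant at these parameters) and
summed, giving the ~87 ms end-to-end loop delay.

### Two-state movement trials

`generate_state_trials` produces 4 s tail-base trajectories (2 s pre + 2 s
post stimulus) from a two-state mixture. Default state parameters: fast
90.8 ± 28.3 mm/s with heading-coherence target 0.9 ± 0.1 (68.1% of trials),
slow 32.5 ± 13.9 mm/s with coherence target 0.1 ± 0.1. Trials are allocated
to states in exact proportion to the weights (seeded shuffle) so a 116-trial
session contains exactly 79 fast trials; speed is constant within a trial.

Headings follow a *slow sweep plus jitter* family: total heading rotation
2π·c over the window plus per-frame Gaussian jitter of sd 0.08·c, with
`c ∈ [0, 1]` the incoherence parameter (c = 0 is a straight line; c = 1
sweeps a full turn, driving the windowed mean resultant length toward
zero). Because the analysis pipeline smooths and renormalizes heading
vectors, the map from `c` to measured coherence is not available in closed
form; it is calibrated once per window geometry by a seeded Monte-Carlo
lookup (fixed internal RNG, 200 simulations per grid point, monotone
cleanup) and inverted by interpolation, so realized coherence matches the
target *in expectation*. Targets below the family's floor (≈0.1) are
realized at the floor.

### Response-latency trials

Motion-energy trials contain a sub-threshold noise baseline (clipped normal,
always < 1000 summed units), a single-frame flash artifact at the true onset
(nominal onset jittered ±0.1 s), and a sustained +3000-unit rise one latency
after onset. Pose trials hold a baseline position (noise sd 0.3 px) and step
6 px at onset. Latencies are drawn from normals truncated to the detection
window; because a truncated normal's mean is not its location parameter, the
location is solved numerically (Brent) so the realized mean matches the
target (4.74 s thermal-style, 0.81 s strongest-optogenetic-style).

## Calibration

The pixel→voltage map is fitted *directly* as two least-squares polynomial
surfaces `Vx(x, y)` and `Vy(x, y)` on the full monomial basis (default
degree 3), with pixels normalized to the observation bounding box for
conditioning and no regularization (the 100 × 100 raster is dense and
well-conditioned). Degree 3 is the lowest degree that drives held-out error
on the simulated rig (degree-2 distortion, 0.8 px spot noise) below ~1 px;
the degree is configurable. Whether to fit V(pixel) directly or invert a
pixel(V) fit is genuinely open; the direct fit makes closed-loop lookup a
single polynomial evaluation and is what `fit_map` does.

The stored fit residual is converted from volts to pixels through the
linear pixel-per-volt gain estimated from the same observations. Held-out
evaluation (`evaluate_map`) steers to target pixels through a supplied
forward model and reports the mean Euclidean pixel error, in px and mm; a
drift beyond 1.94 mm (the weekly platform-drift scale) sets a remap
recommendation flag.

Spot detection returns the intensity-weighted centroid of the connected
component around the global maximum; among equal maxima the brighter
component wins, with exact ties broken toward the smaller (y, x).

## Closed loop

The trigger treats *v* as a standard deviation in pixels (default 1.0) and
uses strict inequalities: population sd(x) < v and sd(y) < v with likelihood
> l at every frame of a trailing window spanning at least *t* seconds
(window length ⌈t·fps⌉ + 1 frames). Windows shorter than *t* are refused
rather than evaluated. After each stimulus the window re-arms from the fire
frame, so one long still epoch cannot fire a burst; a new stimulus
additionally requires strictly more than the refractory interval since the
previous fire time. Targeting always uses the keypoint from the trigger
frame — the system cannot see the future — so hits degrade with delay and
with speed. Hits are adjudicated within a paw-footprint radius of 5 px
(≈2.3 mm at 0.45 mm/px, roughly half a hind-paw width; configurable), and a
spot inside a different paw's footprint counts as keypoint confusion.

The 500 ms refractory used for characterization, the ≥10 min arena spacing
and the >1 min chamber spacing are all protocol presets in configuration,
never hard-coded.

## Multichamber scheduling

Motion energy is the summed absolute frame difference within a chamber ROI
with values below 10 intensity units zeroed. A chamber is idle at a frame
iff *every* transition in the trailing 2 s window is strictly below the
30,000-unit threshold (the windowed-sum alternative reading is noted but not
used). The 30,000-unit threshold is calibrated for 8-bit frames and
230 × 230 px crops and must be re-tuned for other geometries. Idle chambers
outside a 10 s scheduler refractory are chosen uniformly from a seeded
stream; a per-mouse ≥1 min spacing is layered on top as a protocol preset.

## Maze engine

Zone membership uses the snout keypoint (the poke sensor is nose-based);
trajectory analytics use the tail base. The transition graph encodes the
one-way doors: entry corridor → junction is one-way, reward chambers exit
only toward the entry corridor, and corridors may be backed out of to the
junction. An off-zone or ambiguous point keeps the previous zone; a
forbidden jump is logged as a tracking glitch and ignored. Reward-port
timeouts are drawn once per session uniformly in [45, 60] s (per-session
chosen for reproducibility; configurable), and a port re-arms only when the
timeout has elapsed *and* the mouse has exited the chamber since the last
reward. Corridor stimulation fires on entry and then at the corridor's
pulse rate while occupied. Euler-tour condition ordering excludes self-pairs
(a condition never repeats back-to-back); each seeded circuit covers every
ordered pair of distinct conditions exactly once (length n(n−1)+1).

## Analysis pipelines

* **Preprocessing** drops frames with likelihood ≤ threshold (strict >
  retained), removes jumps > 30 px from the last valid frame, and fills
  interior gaps by linear interpolation between anchors that are means of up
  to three valid frames per side; boundary gaps stay missing. The jump
  filter is intended for slow keypoints (tail base): for paw gait
  segmentation it is disabled, because a swinging paw legitimately moves
  more than 30 px between frames and filtering it would merge stance runs.
* **Speed** is Δd/Δt smoothed by a centered 10-sample rolling median,
  converted to mm/s by the scale factor. Categories are lower-inclusive,
  upper-exclusive: [0, 20) stationary, [20, 120) low, [120, 220) medium,
  [220, ∞) high px/s.
* **Gait** labels a frame static when its incoming displacement is below the
  20 px/s stationary threshold; contiguous runs become stance/swing
  segments, and runs touching the series boundary are excluded from duration
  statistics (their true extent is unknown).
* **Motion-energy latency** refines the nominal onset to the largest peak
  within ±0.2 s (the flash artifact), re-windows to ±9.8 s, zeroes the
  artifact sample, denoises with a 3-sample median then a 7-sample Gaussian
  (σ = 2), excludes trials with any ≥1000-unit crossing in (0, 1.5) s as not
  idle, and reports the first crossing in [1.5, 9.8] s. ROI masking and
  sub-3-unit suppression commute; the implementation masks first.
* **Pose latency** uses the likelihood-gated toe keypoint, a [-2, 0) s mean
  baseline, and a strict > 3 px Euclidean threshold in (0, 10] s.
* **Heading coherence** takes per-frame headings from displacements
  (zero-displacement frames carry the last defined heading forward; dropping
  them is the noted alternative), averages unit vectors over a trailing
  10-frame window (partial windows at the start), renormalizes, and reports
  the mean resultant length R over the evaluation window.
* **Clustering** standardizes (speed, coherence), fits a two-component
  full-covariance Gaussian mixture with 10 restarts and a fixed seed, and
  labels the higher-mean-speed component fast-direct — semantic labels never
  depend on component index. A silhouette below zero (or a collapse to one
  component) flags a degenerate clustering.
* **State dependence** computes within-trial post−pre deltas per cluster and
  tests them against zero change (one-sample t) and between clusters
  (Welch's unequal-variance t). All-zero deltas report t = 0, p = 1;
  zero-variance nonzero shifts are reported as undefined with a flag.

## Problem sizes and tolerances

The recovery workflows use 10 × 60 s gait sessions (~2,600 pooled stance
segments), 200 latency trials per pipeline, 116 two-state trials, and a
100 × 100 calibration raster with a ~1,100-point held-out grid — sizes at
which the estimators' standard errors are a few ms / a few mm/s, so
recovery is checked against ±2 SEM (plus one frame interval where a
quantity is frame-quantized). Latency extraction carries an inherent
sub-frame bias (≤ one frame: thresholds cross on the frame grid, and the
Gaussian denoiser advances strong steps slightly), well inside those
tolerances.

## What the generators do not emulate

Simulated keypoints carry no tracker ambiguity: forepaw label swaps,
occlusions, multi-animal crossings and lighting-dependent likelihood drift
are absent (dropout frames at likelihood 0.3 can be injected, but no
confusion rate is modeled). Rendering is a Gaussian-blob cartoon, adequate
for motion-energy arithmetic but not photorealism. Gait is kinematic, not
dynamic — no inertia, turning kinematics or posture. The mouse policy in the
maze simulator is a scripted random walker. Passing recoveries therefore
validate the *pipelines* (calibration, trigger logic, scheduling, latency
extraction, clustering) under stated noise models; they do not certify
tracker performance on real video.
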