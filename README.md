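# stimloop

Closed-loop cutaneous stimulation of freely moving mice — reimplemented
hardware-free, with a virtual rig in place of lasers, galvanometers and
animals.

Studying how skin input shapes behavior requires delivering precise stimuli
to a mouse that is walking or running, which real rigs achieve by tracking
body-part keypoints in real time and steering a laser onto the target paw
with mirror galvanometers. `stimloop` implements the complete software side
of such a system so it can be developed, validated and analyzed at a desk:

* **`core_io`** — pose-table I/O in the three-header-row CSV dialect of
  common markerless pose estimators (scorer / bodyparts / coords), event
  logs, schema-validated configuration.
* **`virtual_rig`** — a simulated mouse with realistic stance/swing gait, a
  frame renderer for motion-energy work, a voltage→pixel optics model with
  smooth nonlinear distortion, a closed-loop delay model (processing
  84 ± 12 ms, actuation 3.3 ± 0.5 ms), and generators for movement-state and
  response-latency trials.
* **`calibration`** — raster acquisition, sub-pixel laser-spot detection,
  and the pixel→voltage mapping: two-dimensional polynomial surfaces
  `Vx(x, y)`, `Vy(x, y)` fitted by least squares to a 100 × 100 raster,
  plus drift QC, chessboard scale factor, and optical uniformity summaries.
* **`closed_loop`** — the trigger rule (keypoint standard deviation < *v*
  pixels with likelihood > *l* throughout *t* seconds), refractory
  accounting, targeting through the calibration map with sampled delays, and
  hit/confusion adjudication against ground truth.
* **`multichamber`** — random-access multi-animal stimulation: per-chamber
  motion energy, idle detection (every transition below threshold for 2 s),
  pseudo-random scheduling with a refractory, and crop/paste-back coordinate
  translation.
* **`maze`** — the alternation-maze task engine: one-way-door topology,
  reward ports that re-arm only after a timeout *and* a chamber exit,
  frequency-paired corridor stimulation, trial segmentation, side-transition
  matrices, and Euler-tour pseudorandomization of stimulus conditions.
* **`behavior_analysis`** — trajectory preprocessing, speed and speed
  categories, stance/swing gait segmentation, motion-energy and pose-based
  response-latency pipelines, heading coherence (mean resultant length *R*
  of smoothed heading unit vectors), two-state Gaussian-mixture movement
  clustering, and paired pre/post state-dependence statistics.

## Worked example

```python
from stimloop import workflows as wf

calib = wf.calibration_heldout_mae(seed=1)
print(f"calibration: held-out MAE {calib.mae_px:.2f} px "
      f"({calib.mae_mm:.2f} mm) from a {calib.n_raster}-point raster")

gait = wf.gait_recovery(seed=1)
print(f"gait: stance {gait.stance_mean_ms:.1f} ms, swing {gait.swing_mean_ms:.1f} ms "
      f"({gait.n_stance} stance segments)")

states = wf.state_cluster_recovery(seed=1)
print(f"states: fast-direct {states.fast_proportion_pct:.1f}% of trials, "
      f"speed {states.fast_speed_mean:.1f} mm/s, coherence {states.fast_coherence_mean:.2f}; "
      f"slow-assess speed {states.slow_speed_mean:.1f} mm/s")
```

prints

```
calibration: held-out MAE 1.00 px (0.45 mm) from a 10000-point raster
gait: stance 350.3 ms, swing 99.9 ms (2643 stance segments)
states: fast-direct 68.1% of trials, speed 92.5 mm/s, coherence 0.89; slow-assess speed 33.7 mm/s
```

Reading the numbers: the fitted pixel-voltage map steers the (simulated)
laser to within about one pixel (≈0.45 mm at the 0.45 mm/px platform scale)
of any requested pixel; gait segmentation recovers the generator's stance
(350 ms) and swing (100 ms) dwell times from raw keypoint trajectories; and
the two-component Gaussian mixture on pre-stimulation (speed, coherence)
features recovers the fast-direct/slow-assess split of movement states with
their per-state speeds and heading coherence.

A thin CLI mirrors these workflows for shell use:

```bash
stimloop simulate --seed 1 --duration 60 --preset medium --out pose.csv
stimloop analyze gait --pose pose.csv
stimloop run-loop --seed 1 --duration 300 --preset stationary \
    --out-events events.csv --out-pose session_pose.csv
stimloop run-maze --seed 1 --duration 3600 --out trials.csv
```

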