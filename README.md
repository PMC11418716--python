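# stairreach

Event detection and kinematic profiling for the mouse **Staircase test**
(skilled forelimb reaching), computed from markerless pose-estimation
trajectories.

In the Staircase test a mouse stands on a central platform and reaches
for sugar pellets placed in eight descending wells on each side of the
box — the standard assay for lateralized forelimb deficits after
experimental stroke. Markerless tracking (e.g. DeepLabCut) of
side-view video yields per-frame `(x, y, likelihood)` triplets for each
forepaw and each well's pellet. The classical readout — pellets eaten
per session — ignores *how* the animal reached. `stairreach` turns the
raw trajectories into a per-side behavioral and kinematic profile:

* **cleaning** — rejection of non-physiological trajectory jumps
  (displacements beyond 6 × SD of the landmark's frame-to-frame
  displacement distribution), interpolation of single-frame dropouts
  from the two nearest valid frames, and a centred 10-frame moving
  mean;
* **event detection** — reaching attempts and forepaw slips found where
  a successive maximum/minimum pair of the paw's signed outward
  velocity exceeds 1.5 px/frame, with event windows bounded by the
  enclosing zero crossings. A horizontal-to-vertical displacement
  ratio Δx̄/Δȳ < 1.5 classifies an event as a slip (a vertical drop off
  the platform edge), otherwise as a reach;
* **phase segmentation** — each reach splits at its inversion point
  (the paw's turning point) into a reach phase toward the pellet and a
  retraction phase away from it; the reach target is the well nearest
  the paw at inversion;
* **pellet outcomes** — a frame-by-frame pellet presence signal per
  well (likelihood ≥ 99 %, debounced against paw occlusion) detects
  removals, which are matched in time to reaching attempts; the joint
  pellet/paw trajectory after removal separates successful retrievals
  from drops;
* **kinematics** — per event and phase: path length
  `s = Σ √(Δx² + Δy²)`, duration, instantaneous velocity
  `v = √(Δx² + Δy²)/Δt` and acceleration `a = Δv/Δt` (min, max, mean),
  converted to cm and s; slip depth below the platform edge.

Per session and body side this yields **30 outcome parameters**:
5 event counts/scores — among them the success coefficient

```
k_success = reaches_successful² / reaches_all
```

(`reaches_all` counts only reaches toward wells not yet emptied;
squaring rewards retrieving more pellets in fewer attempts) — plus
8 kinematic summaries × 3 scopes (full attempt, reach phase,
retraction phase) and the session-mean slip depth.

A fully ground-truth-annotated **synthetic session generator** is part
of the package: minimum-jerk out-and-back reach strokes, vertical
slips, occlusion dips and likelihood collapse of pellet landmarks,
ballistic drop tracks, Gaussian pixel noise, and single-frame
spike/dropout artifacts. It drives the test suite and the validation
workflow below.

## Worked example

Simulate a session, analyze it, and score the detections against the
generator's ground truth:

```
$ stairreach simulate --seed 4 --out sim
seed=4 frames=8667 reaches=100 slips=20 -> sim

$ stairreach run --input sim/poses.csv --layout sim/layout.yaml \
      --out out --animal m01 --day pre
frames=8667 reaches=100 slips=20 removals=14 -> out

$ stairreach validate --events out/events.tsv --truth sim/truth.tsv \
      --removals out/removals.tsv
{
  "tolerance_frames": 10,
  "kinds": {
    "reach": {"n_truth": 100, "n_detected": 100, "n_matched": 100,
              "sensitivity": 1.0, "precision": 1.0, "bin_accuracy": 1.0},
    "slip":  {"n_truth": 20, "n_detected": 20, "n_matched": 20,
              "sensitivity": 1.0, "precision": 1.0, "bin_accuracy": 1.0}
  },
  "removal": {"n_truth": 14, "n_detected": 14, "n_matched": 14,
              "sensitivity": 1.0, "precision": 1.0}
}
```

All 100 injected reaches, 20 slips and 14 pellet removals were
recovered within ±10 frames of their true start. `out/features.tsv`
holds the 30-parameter rows; for the right side of this session:

| parameter | value | meaning |
|---|---|---|
| `reach_events` | 50 | reaching attempts detected |
| `slip_events` | 10 | platform slips |
| `pellet_events` | 7 | pellets removed from wells |
| `success_events` | 5 | successful retrievals (2 removals were drops) |
| `k_success` | 0.862 | 5² / 29 reaches toward still-baited wells |
| `attempt_duration_s` | 0.678 | mean reach duration |
| `attempt_velocity_mean` | 7.125 | mean paw speed, cm/s |
| `reach_distance_cm` | 2.436 | mean reach-phase path length |
| `slip_depth_cm` | 0.373 | mean vertical slip below the platform |

The same `run` command accepts real pose tables (DLC-style CSV with a
3-level header, or HDF5) with a YAML chamber layout describing well
centers, platform edge, px/cm scale and frame rate; every analysis
threshold can be overridden with `--set key=value`.

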