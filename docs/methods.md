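# Methods

This note documents the processing model behind `stairreach`: what each
stage assumes, the parameters that matter, the numerical choices, and
what validation on synthetic sessions does and does not establish.

## Coordinate and indexing conventions

Coordinates are 0-based pixel centers in image convention — y grows
downward, so "the paw drops below the platform" means y increasing past
`platform_y`. Frames are 0-based; all event windows are half-open
`[start, end)`, so a duration is always `end − start` frames. Pixels
and frames convert to centimetres and seconds through the chamber's
`px_per_cm` scale and frame rate (Δt = 1/fps; 10 ms at the nominal
100 Hz). The nominal chamber image is 320 × 240 px; a four-chamber
640 × 480 recording is split with `split_chambers`, which only
translates coordinates (pairwise landmark geometry is preserved
exactly).

## Trajectory cleaning

Cleaning applies to paw landmarks only. Pellet (well) landmarks are
deliberately passed through raw: their likelihood trace *is* the
pellet-presence signal, and interpolating or smoothing it would
manufacture pellet evidence.

1. **Confidence floor.** Paw frames with tracking likelihood below
   `paw_likelihood_floor` (default 0.6, a conventional tracking
   confidence floor) are marked missing before anything else.
2. **Jump rejection.** The threshold is `jump_sd_multiplier` (default
   6) times the SD of the landmark's frame-to-frame 2D displacement
   magnitudes, computed once over initially valid frames — a single
   filter pass, not iterated. The trace is then walked forward and each
   frame compared against the most recent *accepted* frame, with the
   allowance scaled linearly by the frame gap `g` (a physiological paw
   can cover `g × threshold` px in `g` frames). Consequences worth
   knowing: an isolated spike rejects exactly the spike frame; a
   run of consecutive spikes is rejected frame by frame; and a genuine
   fast frame that exceeds the threshold does not cascade into
   rejecting the rest of the movement. The rule uses displacement
   *magnitude*; per-axis deviation is the plausible alternative reading
   and would flag a superset on axis-aligned jumps. A frozen landmark
   (zero displacement SD) has no jumps by definition. Because the
   threshold adapts to the session's own movement statistics, a session
   in which the animal barely moves gets a hair-trigger threshold —
   that is a property of the filter, not of this implementation.
3. **Gap filling.** Invalid runs of at most `max_gap_fill` frames
   (default 1: dropouts typically affect single frames) enclosed by
   valid frames are filled with the coordinate means of the two nearest
   valid frames. Longer runs are left invalid and split the trace into
   independent usable spans — no data is invented across occlusions.
   Leading/trailing runs are never filled. Valid frames are never
   modified.
4. **Smoothing.** A centred moving mean of `smoothing_window` frames
   (default 10) per usable span, truncated and renormalized at span
   edges. An even window is symmetrized with half-weight end taps
   (weights ½,1,…,1,½ over w+1 points) so the filter has exactly zero
   phase delay; an off-centre 10-tap window would shift every event
   boundary by half a window (~50 ms) and corrupt phase segmentation.
   The output is a convex combination of in-span inputs, hence bounded
   by the span's min/max and exact on linear segments.

## Event detection

Both reaching attempts and platform slips are out-and-back excursions
of the paw from its rest posture: out toward a well (reach) or down off
the platform edge (slip), then back. Detection therefore runs on a
single **signed outward velocity** signal: the frame derivative of the
paw's Euclidean distance from its rest posture, where the rest posture
is the per-axis median of the paw position over the session (the paw
spends most of a session at rest, so the median is insensitive to the
excursions themselves). This realises "velocity along the movement's
dominant axis" with an unambiguous sign — positive away from rest,
negative returning — and treats reaches and slips identically.

A candidate event is a local maximum of this signal at or above
`velocity_threshold` (default 1.5 px/frame) followed by the next local
minimum at or below the negated threshold: movement away, then back.
The window then extends outward to the enclosing zero crossings. On
noisy data the signal hovers around zero at rest, so the numerical
zero is a small band, `zero_band_px` (default 0.15 px/frame, 10 % of
the velocity threshold): the boundary is the first sample at or below
the band. This anchors boundaries at movement onset instead of letting
them random-walk through rest noise — the standard onset convention in
velocity-threshold movement segmentation. Overlapping windows merge
into one event; windows shorter than `min_event_frames` (default 3,
30 ms) are discarded as flicker. Raising the velocity threshold can
only lose events on physiological signals; on adversarial noise the
merge step can occasionally reorganize windows, which is why the
monotonicity property is stated for separated events.

Classification: over the window, `ratio = mean|Δx| / mean|Δy|`. A
ratio below `slip_ratio_threshold` (default 1.5) is a slip, anything
else a reach; zero vertical displacement gives ratio +∞, a reach.
Pellet information plays no role in this decision. Slips are scored
only when the paw starts within `platform_band_px` (default 15 px) of
the platform edge — a vertical drop that begins far below the platform
is grooming or chamber entry, not a slip off the platform. Events
during chamber entry are thereby approximately, not perfectly,
excluded.

Each reach splits at its **inversion point** — the frame of greatest
distance from rest inside the window, equivalently where the outward
velocity crosses zero between the paired extrema. For merged
multi-peak windows the deepest turning point wins. Reach phase =
`[start, inversion)`, retraction = `[inversion, end)`. A window with
no interior turning point (monotone drift) is discarded with a
warning. The reach target is the well with minimum Euclidean distance
to the paw at inversion; ties break to the lowest well index.

## Pellet outcomes

Per well, the tracking likelihood of the pellet landmark acts as a
pellet-existence probability. Presence is `probability ≥
pellet_prob_threshold` (default 0.99) with debouncing: a
below-threshold run shorter than `removal_debounce` (default 5 frames,
50 ms) never toggles presence, because the paw passing over the well
kills likelihood transiently and 99 % is a hair-trigger without
debouncing. The first sufficiently long run opens a *provisional*
removal at its first frame; it is *confirmed* only if likelihood does
not recover **at the well** (within `well_radius_px`, default 10 px, of
the well center — the spatial extent of a well is otherwise undefined)
before the next reaching attempt. Recovery at the well means occlusion,
not removal. Confirmed presence is monotone: once removed, a well stays
empty, and at most one removal per well per session is possible.

A confirmed removal is matched to the reach whose window contains the
removal frame; failing that, to the nearest preceding reach that
targeted the same well; failing both it is flagged *spontaneous*
(counted as a pellet event, never as a success). From the removal frame
to the next reach start, the joint pellet/paw trajectory decides the
outcome:

* **drop** — the pellet landmark is re-acquired clear of every well's
  radius with net downward displacement relative to its source well,
  or is seen moving downward while separated from the paw by more than
  `divergence_px` (default 15 px);
* **success** — otherwise: the pellet either vanished before the next
  reach (eaten) or co-moves with the paw (carried). The divergence
  criterion is the least constrained rule in the pipeline — no numeric
  criterion exists for "common trajectory of pellet and paw" — so both
  constants are config-exposed and covered by dedicated tests.
* **no contact** — a reach with no matched removal.

A pellet that drops into a lower well is treated as unavailable rather
than re-entering the pellet pool.

## Kinematics and the feature row

Velocity samples live on frame intervals `[f, f+1]`; an interval
belongs to the reach phase when `f < inversion`. Phase durations and
path lengths are therefore exactly additive to the full attempt
(asserted to 1e-9 in the tests). Per scope (full attempt, reach,
retraction): path length, duration, mean velocity (= distance /
duration), mean signed acceleration, and min/max of instantaneous
velocity and acceleration. Velocity is speed (≥ 0), so its minimum is
the near-zero value at the turning point; a signed component would be
the alternative reading. Windows shorter than 3 frames have no
acceleration samples and yield NaN. Slip depth is the deepest vertical
excursion below the platform edge within the event, floored at 0.

The 30 parameters per session side: `k_success`, `success_events`,
`pellet_events`, `reach_events`, `slip_events`; 8 kinematic summaries ×
3 scopes (names `<scope>_<feature>`, e.g. `attempt_duration_s`,
`reach_distance_cm`, `retraction_velocity_max`); `slip_depth_cm`.
Session aggregation is the arithmetic mean over the side's reaches
(slips for depth). Missing values are NaN, never zero: a session
without reaches has no mean velocity, and `k_success` is undefined (not
0) when `reaches_all = 0`, because never attempting is not the same
performance as failing. `reaches_all` counts only reaches toward wells
not yet emptied at the reach's start. A `normalized_to_baseline`
utility divides any feature by the animal's same-side baseline-day
mean; it is a post-hoc view, not a 31st column.

## Synthetic sessions

The generator renders the same pose-table format the reader ingests.
Reaches are minimum-jerk out-and-back strokes from the rest posture to
a target well with an out/back asymmetry of 0.35–0.5, so inversion
detection is never tested only on the symmetric special case; peak
outward speeds are drawn from 4–9 px/frame (10–22 cm/s at the default
scale — ordinary mouse reach speeds). Slips are vertical min-jerk
step-and-returns of 22–42 px depth. The default session carries ~50
reaches and ~10 slips per side with 40–120 rest frames between events
(~80–90 s of video), 5 successes and 2 drops per side at distinct
wells, 1 px Gaussian coordinate noise, and Poisson spike (30–80 px,
single-frame) and dropout artifacts at 2 per 1000 frames each —
artifact frames kept non-adjacent so each is the single-frame glitch
the cleaning stage is specified to repair. Pellet likelihood sits near
1, dips to 0.4 for 3 frames while the paw is over the target well,
collapses permanently at removal; dropped pellets reappear 8 frames
later on a ballistic downward track, and 30 % of successes show a
visible carried-pellet track for ~7 frames. Everything is a pure
function of the seed.

Staircase geometry: wells step 16 px outward and 6 px downward per
step from the central platform (side view), so reaching is
horizontal-dominant (displacement ratios ≈ 2.7–2.9) and slipping is
vertical — the geometric premise of the ratio classifier. Cohort
phenotypes scale these conditions: `mcao_like` multiplies event
durations up to a bradykinesia factor (default 1.5) across days,
`pt_like` multiplies the slip count (default 2.5×) and converts
successes to drops, `sham` is stationary.

What the generator does **not** emulate: body/torso posture and its
interaction with the paw, pellet-to-pellet visual confusions,
likelihood decay with motion blur, correlated multi-frame tracking
failures, chamber-entry movements, or photorealistic appearance.
Perfect sensitivity on synthetic sessions therefore demonstrates the
correctness of the event logic under the stated noise model, not
performance on any particular video corpus.

## Validation protocol

Detections and ground truth are matched greedily, one-to-one, by
nearest start frame within ±10 frames (`event_match_tolerance`),
separately per side and event kind; removals additionally match per
well on the removal frame. Sensitivity = matched truth / all truth;
precision = matched detections / all detections; binwise accuracy
compares event occupancy in 1-s bins. The acceptance script pools all
three sensitivities over 20 default sessions (~2000 reaches, ~400
slips, ~280 removals) and reports them in percent.

Two measurement biases are inherent and documented rather than hidden:
the centred 10-frame moving mean spreads movement onset by up to half a
window, so detected boundaries sit within ~5 frames of truth even
without noise; and smoothing clips the sharp slip bottom, biasing slip
depth low by roughly a quarter at default slip speeds. Both are
properties of the published smoothing choice, not of the detector.

## Known limitations

* The rest posture is estimated per session from the median paw
  position; sessions in which the paw rests in several distinct places
  would blur the outward-velocity signal.
* Slips during chamber entry are only approximately excluded by the
  platform band.
* The drop/carry discrimination depends on two spatial constants
  (`well_radius_px`, `divergence_px`) with no published values; they
  are config-exposed and should be calibrated per rig.
* Group statistics (discriminant analysis, ANOVA, correlations) are
  out of scope; the package ends at the per-session feature table.
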