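# Methods

This note documents the models, parameter choices and known limitations
behind `gaitrig`: what each stage assumes, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Coordinate conventions and units

Everything internal is in meters and seconds.  Gait outputs are converted
at reporting time to the units clinical tables use: cm for lengths, s for
times, cm/s for speed.  The global frame is defined by the origin marker:
it lies flat on the floor, its first in-plane edge is the walking-hall X
axis, and its plane normal is the vertical Z (up).  Sensor camera frames
are x-right, y-up, z-along-the-optical-axis; a `RigidTransform` is always
a proper rotation plus translation (orthonormal to 1e-9, det = +1), so
distances are preserved exactly and reflections can never enter the
chain.

## Calibration

* **Rigid Procrustes.** Marker templates are registered to observed
  corners with the SVD (Kabsch) solution; the smallest singular
  direction's sign is corrected so the rotation is proper.  No scale is
  fitted — a scaled observation leaves residual by design, which the
  tests use to confirm rigid-only fitting.  Collinear corner sets (rank
  < 2 after centering) are rejected: they leave a rotation degree of
  freedom unconstrained.
* **Markers.** The template is the four salient corners of a square
  marker, side 0.30 m by default (configurable), ordered
  counter-clockwise from the dent corner.  A calibration capture is
  modeled as one second of frames (30 noisy corner sets per visible
  sensor–marker pair); the pairwise fit pools all frames of a pair.
  Pooling matters: a single 4-corner observation at 5 mm corner noise
  caps pose accuracy near 1.3° median rotation error for purely
  geometric reasons (per-axis angle error ≈ σ divided by the corner
  spread, ~0.95° per axis at side 0.30 m), while the pooled fit reaches
  ~0.2° / 0.7 mm for directly-connected sensors.
* **Chaining.** Shortest paths in the bipartite visibility graph are
  found by breadth-first search with ties broken by ascending node
  identifier, so results are deterministic.  A disconnected graph raises
  an error naming every sensor without a path to the origin marker.
  Chained error grows with path length (each hop multiplies in an
  estimation error); the noisy-calibration test asserts exactly this
  monotonicity.
* **ICP refinement.** Point-to-point ICP with nearest neighbours from a
  k-d tree; correspondences are rejected beyond `max_pair_distance`
  (0.10 m default) and additionally beyond 3× the median match distance,
  which keeps frustum-boundary mismatches from dragging an already
  correct pose.  Sensors are refined one at a time in ascending
  chaining-path-length order against the merged cloud of already-fixed
  sensors; the origin-nearest sensor anchors the frame and never moves.
  Whether the original system refined poses pairwise-sequentially or
  jointly is not documented anywhere we could rely on; the
  anchor-sequential scheme is this package's choice, made for
  determinism and because it cannot rotate the global frame.  A sensor
  with fewer than `min_pairs` (20) matches is skipped with a warning and
  keeps its chained pose.

## Fusion

* **Resampling.** Linear interpolation onto a uniform 30 Hz grid anchored
  at the latest stream start (the intersection of time ranges), so all
  resampled streams share phase exactly.  A grid sample is valid only
  when both flanking raw frames are `tracked` and at most `max_gap` =
  0.2 s apart (≈ 6 frames).  `inferred` joints are treated as missing:
  inferred positions come from the tracker's prior, not from
  measurement, and are not trusted for gait.  Whether a sample with only
  one tracked flank should count was an open choice; requiring both is
  the conservative rule and is what the validity masks encode.
* **Averaging.** Sensors are weighted equally — nothing is known about
  their relative noise — and each joint/grid sample averages only the
  sensors valid there, recording the contributing count.
* **Smoothing.** Zero-phase (forward–backward) Butterworth low-pass,
  design order 4, cutoff 6 Hz, applied per coordinate to each contiguous
  valid segment; segments shorter than 3·(order+1) samples pass through
  unchanged, and validity masks are never altered.  The original
  processing names no filter; this is the conventional gait-analysis
  choice.  Gait signal content lives below ~6 Hz at normal cadence
  (~0.9 Hz stride frequency), so the passband loss is < 1% while
  frame-rate noise is strongly attenuated.

## Gait analysis

* **Walking frame.** Forward = unit horizontal direction of the total
  mid-ankle displacement (≥ 1 m required); lateral = vertical × forward.
  All parameters are therefore invariant under global rotation and
  translation of the scene, which is tested.
* **Events.** Crossings of the ankles' forward positions are detected
  with a Schmitt trigger: the sign of d = left − right is "held" once
  |d| exceeds the hysteresis band (default 0.02 m); a zero crossing is
  kept pending and confirmed as an event only when |d| exceeds the band
  on the opposite side, at the first crossing's interpolated time.
  Chatter inside the band collapses into one event, and — unlike naive
  re-arming — a gap-displaced event can never swallow the next genuine
  crossing (this failure mode appears with one-sided reconstruction,
  where occlusion gaps sit exactly at the crossings).  A terminal return
  of d exactly to zero counts as an event; leading zeros do not.  The
  passing foot is the one with larger forward-speed magnitude (central
  differences); exact ties fall back to the foot with smaller
  forward-velocity variance over ±100 ms being stance, and are flagged.
* **Placements.** One placement per event: the stance ankle's projected
  position at the event time, interpolated over valid samples if the
  exact instant is missing.  During stance the forward position is a
  plateau, so this reads the footfall position; it is the single largest
  interpretive decision in the pipeline and is isolated in
  `extract_placements` so alternatives (e.g. plateau-median) can be
  swapped.  Repeated stance feet (a data-quality defect) drop the event
  with the smaller crossing slope and flag the survivors.
* **Parameters and exclusions.** Step width is the unsigned lateral
  distance between consecutive placements; the alternative reading
  (simultaneous feet positions at placement time) differs only by the
  swing foot's lateral excursion and was not adopted.  With a left start
  foot, the first left step and the first right stride are removed
  everywhere, and walking speed is Σ included step length / Σ included
  step time — an identity the tests assert exactly.

## Agreement statistics

* Bias = mean(A−B); RPC = 1.96·SD(A−B) (sample SD, n−1); CV = SD(A−B) /
  grand mean of the pairwise means × 100.  The descriptive text of the
  original tables calls RPC "the standard deviation of the difference"
  while the footnote says 1.96·SD; the printed RPC/CV ratios are
  consistent only with 1.96·SD, so that is implemented and the raw SD is
  also exposed (`sd_diff`).
* ICC(A,1) follows the McGraw–Wong two-way absolute-agreement
  single-measures formula computed from the ANOVA mean squares, with
  systems as the k = 2 columns; at the single-step level each step is a
  row, at the subject levels each subject is a row.  The implementation
  is cross-checked against an independent from-scratch mean-squares
  oracle (to 1e-10) and against pingouin.
* Category boundaries are half-open intervals covering [0, 1] — the
  printed ranges leave gaps (0.59→0.6, 0.74→0.75) which the half-open
  convention closes; negative ICCs report as "poor" with a flag.
* Step pairing across systems: chronological rank when counts match,
  greedy nearest-event-time matching within 0.2 s otherwise, with
  unmatched steps dropped and counted.  External parameter tables can be
  ingested through `agreement.load_parameter_table` with a column map.

## The synthetic-data generator

* **Rig.** Paired left/right sensors per row: rows 2.5 m apart along the
  walk, sensors 2 m apart across it, rotated inward 35°, mounted at 1 m;
  frustum 70°×60°, depth 0.5–4.5 m.  With three rows the corridor
  centerline is covered over ≈ 9.4 m and consecutive rows overlap by
  ≈ 1.9 m — the overlap a walker needs for the next row to acquire the
  body before the previous row loses it.
* **Walker.** A 25-joint stick figure driven entirely by the ankles:
  forward position exactly constant in stance, one stride advanced per
  swing along a raised cosine (C¹ at the stance boundaries; a sin² lift
  of 5 cm in swing); all other joints are kinematically slaved to the
  ankle/pelvis motion, adequate because the analysis uses only ankles.
  The walker starts in steady state with the start foot trailing by one
  step and swinging first, so each of the 2n swings produces exactly one
  crossing and the commanded step length/width/time translate exactly
  into ground-truth placements and parameters (the generator emits them
  alongside the streams, satisfying the walking-speed identity by
  construction).  Defaults: 0.73 m steps, 0.12 m width, 100 steps/min,
  duty factor 0.6, 5 strides — a comfortable ~7 m walk.  Cohorts draw
  per-subject commands around these means (SD 5 cm / 2 cm / 8 steps/min).
* **Corruption.** Isotropic joint noise (default σ = 1 cm); timestamp
  jitter ≤ 2 ms (the clock-synchrony budget of a PTP-synchronized rig)
  plus a per-sensor frame-rate wobble around 30 Hz and a free-running
  phase; frustum culling to `untracked`; self-occlusion dropout — a
  far-leg joint is untracked when its line of sight passes within 8 cm
  of the near leg's hip–ankle segment, a geometric stand-in for the
  skeleton fitter's failure, not a claim about the fitter itself; and a
  lateral surface pull of magnitude b toward the sensor's side of the
  walk, modeling estimates that sit closer to the body surface the
  sensor actually sees.  The pull's real-world magnitude is only
  qualitatively characterized, so b is a free parameter (0 by default;
  1.5 cm in the bias experiments).
* **What the simulator does not emulate.** Per-step biological
  variability within a recording (each recording walks at its commanded
  parameters exactly), soft-tissue and clothing artifacts, tracker
  latency, multi-person scenes, and the skeleton fitter's actual error
  process.  Passing tests therefore demonstrate the correctness of the
  geometry, fusion logic and statistics under a controlled error model —
  not the field accuracy of any particular sensor.
* **A deliberate mechanistic finding.** With the pull and occlusion both
  active, two-sided fusion cancels the lateral position offset almost
  exactly (< 0.1 b versus ≈ b for left-only), but the *step width* is
  pushed outward by ~2b·(valid-phase fraction) in the two-sided case:
  at each crossing the stance ankle is occluded from the contralateral
  sensors, so its placement is read from same-side sensors only, each
  pulling outward.  For a mirror-symmetric rig one can show the mean
  width bias of left-only and two-sided reconstruction must coincide for
  any per-sensor error model with symmetric validity; width improvements
  from two-sided tracking are therefore variance effects (smaller RPC,
  higher correlation), not mean-bias effects.  The agreement tables the
  acceptance script produces show exactly this signature.

## Problem sizes

The test suite and acceptance script choose sizes that keep a full run on
one CPU within a few minutes while leaving the statistics meaningful:
50 calibration replicates at 5 mm corner noise, 20 noisy gait recordings,
5 replicates per fusion subset in the bias experiment, a 10-subject ×
10-trial cohort (100 recordings, ~1600 paired steps) for the agreement
tables, and 30 seeded datasets for the ICC oracle.

## Known limitations

Straight overground walks only (no turning, no treadmill); single tracked
body; heel-strike/toe-off events are out of scope (crossing events are
temporal midstance proxies, which is why step *time* is insensitive to
the placement scheme); the ICP refinement assumes a static, geometrically
rich scene; and agreement levels assume recording identifiers of the form
`subject/trial` when subject averaging is requested.
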