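# gaitrig

Multi-depth-sensor markerless gait analysis: extrinsic calibration of a
corridor rig of skeleton-tracking depth sensors, fusion of their 25-joint
streams into one skeleton, extraction of spatiotemporal gait parameters,
and the agreement statistics used to validate such a system against an
optical motion-capture reference.

**Who it is for.** Movement scientists and clinical-gait engineers who
want to assemble an overground gait-capture corridor from consumer depth
sensors (each delivering 25-joint skeletons at ~30 Hz within a 70°×60°,
0.5–4.5 m frustum) instead of a fixed optical lab — and who need the full
analysis chain, including a way to test it without hardware.  A built-in
synthetic-data module generates every input the pipeline consumes (rig,
calibration markers, point clouds, multi-sensor skeleton streams of a
parameterized walker) with exact ground truth.

## The method

**Calibration.** Coded planar markers are laid out in the scene; each
sensor that sees a marker yields the marker corners in its local frame,
and a rigid Procrustes fit (SVD with the determinant forced to +1 — no
scale, no reflection) gives the marker→sensor transform.  The relation
"sensor *s* sees marker *m*" is a bipartite graph *G* = (*V*, *E*),
*V* = *M* ∪ *S*.  If *G* is connected, every sensor can be chained to the
origin marker by composing transforms along a path; the shortest path is
used because every hop adds estimation error.  An optional point-to-point
ICP pass against overlapping point clouds refines the chained poses.

**Fusion.** Streams are mapped into the global frame, resampled to a
uniform 30 Hz grid by linear interpolation (a sample is valid only when
both flanking frames are *tracked* and ≤ 0.2 s apart; *inferred* joints
count as missing), averaged with equal sensor weights per joint and grid
sample, and smoothed with a zero-phase Butterworth low-pass (order 4,
6 Hz).

**Gait parameters.** Foot events are the crossings of the two ankles'
forward positions (one foot passing the other).  Each event yields a foot
placement — the stance ankle's position at the event.  Then, in the
field's standard definitions: step length = forward distance between
consecutive opposite-foot placements; step width = their unsigned lateral
distance; step time = their separation in time; stride length = forward
distance between consecutive same-foot placements; walking speed =
Σ step length / Σ step time per recording.  Because subjects start with
the left foot, the first left step and the first right stride are
excluded as acceleration artifacts.

**Agreement statistics.** Two systems' parameters are paired per
recording and compared with Pearson's *r*, the Bland–Altman quantities
(bias = mean difference; RPC = 1.96·SD of the differences; CV = SD of the
differences as % of the grand mean), and the intraclass correlation for
absolute agreement with single measures,

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)),

classified as poor [0, 0.4), fair [0.4, 0.6), good [0.6, 0.75) or
excellent [0.75, 1].  Comparisons run at three levels: single steps per
side, per-subject averages per side (AV), and per-subject averages pooled
over sides (AV … AVG).

## Worked example

Simulate the default rig (three sensor rows 2.5 m apart, 2 m across,
rotated inward 35°), calibrate it from floor markers, capture a commanded
walk through six noisy sensors, and recover the gait parameters:

```python
import numpy as np
from gaitrig import (GaitCommand, CorruptionModel, simulate_gait, simulate_rig,
                     simulate_marker_observations, corrupt_streams, calibrate)
from gaitrig.simulate import default_marker_poses
from gaitrig.pipeline import fuse_recording, gait_from_series
from gaitrig.config import PipelineConfig

cfg = PipelineConfig()
rig = simulate_rig()                      # 3 rows x 2 sensors, 35 deg inward
markers = default_marker_poses()          # floor markers; marker 1 = origin
observations, templates = simulate_marker_observations(rig, markers, seed=0)
calib = calibrate(observations, templates, origin_marker_id=1)
print("chain lengths:", {s: len(calib.paths[s]) - 1 for s in calib.sensor_ids()})

cmd = GaitCommand(step_length=0.73, step_width=0.12, cadence=100)
truth = simulate_gait(cmd)
streams = corrupt_streams(truth, rig, CorruptionModel(joint_noise_sigma=0.01), seed=42)
fused = fuse_recording(streams, calib, cfg, subset="both")
steps, strides, summary, _ = gait_from_series(fused, cfg)
print(f"steps: {len(steps)}, mean step length {np.mean([s.step_length for s in steps]):.2f} cm,"
      f" width {np.mean([s.step_width for s in steps]):.2f} cm,"
      f" time {np.mean([s.step_time for s in steps]):.3f} s")
print(f"walking speed {summary.walking_speed:.2f} cm/s"
      f" (commanded {100 * cmd.step_length / cmd.step_time:.2f})")
```

Output:

```
chain lengths: {1: 1, 2: 1, 3: 3, 4: 3, 5: 5, 6: 5}
steps: 8, mean step length 73.06 cm, width 12.34 cm, time 0.600 s
walking speed 121.73 cm/s (commanded 121.67)
```

The first row's sensors see the origin marker directly (path length 1);
the farther rows chain through one or two intermediate markers (3 and 5
hops).  With 1 cm joint noise on every sensor the fused reconstruction
recovers the commanded 73 cm / 12 cm / 0.6 s walk to within a few
millimeters and milliseconds.

The same pipeline is scriptable from the shell:

```sh
gaitrig simulate --seed 1 --n-subjects 10 dataset/
gaitrig run --subsets both,left_only dataset/ out/
```

which writes calibration, fused series, per-step gait-parameter CSVs and
agreement tables (CSV + aligned text) comparing the rig against the
dataset's reference trajectories, for two-sided and left-only
reconstruction.

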