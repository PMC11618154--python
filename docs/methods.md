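# Methods

This note documents the models and procedures implemented in `gazecal`,
the choices made where the design was genuinely open, and what the
synthetic participant does and does not capture about real data.

## Coordinate model and angular computations

Screen positions are canonically *normalized* coordinates (origin
top-left, x rightward, y downward, screen = [0,1]²), stored unclamped so
off-screen gaze stays representable. For angular quantities the screen
is modeled as a planar rectangle whose center sits a configurable
viewing distance (default 600 mm, typical of desktop tracker setups)
directly in front of the nominal eye position, normal toward the
participant. Two angular parameterizations are used:

* `angular_offset(a, b)` — the true 3-D visual angle subtended at the
  eye between two screen points (atan2 of cross/dot products; accurate
  at all separations). Used for accuracy and RMS-S2S.
* `screen_to_angular` — tangent-plane horizontal/vertical gaze angles,
  with `angular_to_screen` its exact inverse. Used for STD precision
  (per-axis variances need axis-aligned angles) and for injecting
  angular noise in the simulator.

When per-sample 3-D eye origins are unavailable (minimal logs), the
nominal viewing position is used; when available they can be passed to
the metric functions. Consequence of the tangent-plane construction:
translation invariance of STD is exact in angle space and holds only to
O(θ³) after projection through the screen — a ~0.2% effect for a 4°
shift, which the tests budget for.

## Gaze streams and filtering

A gaze sample is one timestamped binocular measurement; an invalid eye's
position must be ignored by every consumer (property-tested by fuzzing
invalid samples' positions). Binocular averaging falls back to the
single valid eye so unilateral data loss does not stall gaze-contingent
logic. Controllers smooth the stream with a trailing moving-average
filter; the averaging window is not dictated by the interface
description, so it defaults to 200 ms — short enough for responsive
dwell detection at 60–600 Hz — and is configurable (a mean rather than a
median filter, the simpler and more common choice). The operator-facing
gaze-history window defaults to 500 ms.

## Data-quality metrics

* **Accuracy** is the *mean* per-sample angular offset per validation
  point (a median alternative is exposed via configuration); medians
  enter only at the session-summary level, across sessions.
* **RMS-S2S** excludes sample pairs bridging an invalid gap rather than
  interpolating across it, to avoid manufacturing artificial jumps.
* **STD** is the root of the summed per-axis population variances of the
  gaze angles (RMS deviation from the mean position), so for isotropic
  per-axis noise σ it equals σ√2 and RMS-S2S/STD → √2 on i.i.d. data.
* **Data loss** uses the expected-sample denominator
  `round(duration · rate)` and clamps to [0, 100]; if the nominal rate
  is unknown it falls back to the received-sample count and flags the
  report.
* The "average" eye channel is computed on the per-sample
  binocular-average position signal, not as the mean of the two eyes'
  metrics (the published per-eye/average values are inconsistent with a
  simple mean of metrics).
* Aggregation over validation points is an unweighted mean over the
  points for which data is available, regardless of per-point sample
  counts. Session summaries report per-participant medians with min–max
  ranges and per-group unweighted means of the median binocular-average
  accuracy.

## Calibration model

A real tracker fits its calibration internally; the stand-in fits, per
eye, a least-squares mapping from raw to true normalized screen
coordinates over all samples of the *usable* points (≥ 10 valid samples
for that eye, configurable). The mapping family ladders with the usable
point count — 1 point: translation; 2 distinct points: similarity;
≥ 3 non-collinear: full affine — because the automated procedures
calibrate from as few as one or two locations and the fit must degrade
gracefully. Degenerate layouts (coincident or collinear raw centroids)
fall back to the next-lower family with a note. Plain least squares is
the default (commercial fits are opaque; simple and documented beats
clever here); an optional trimmed refit drops the worst 20% of
residuals once. There is no published criterion for when a tracker
declares a calibration failed, so a residual-RMS sanity bound
(default 0.25 normalized units) is the proxy. Monocular fits overlay
only the selected eye's mapping, leaving the other untouched.
Calibration results and snapshots serialize to JSON exactly (float
repr), so snapshot/load round-trips are bitwise-identical.

## Session state machine

Operator inputs and controller decisions share one dispatch path, making
manual and automated operation behaviorally identical and fully
loggable. Target lifecycle: `not_collected → enqueued → showing →
collecting → {collected, not_collected}`; enqueued targets form a FIFO
queue promoted when nothing is active, and at most one target is ever
showing/collecting. Collection windows are wall-clock in stream time
(default 600 ms), so behavior is sampling-rate independent; a window
succeeds when ≥ `min_samples_per_point` valid samples arrive for at
least one selected eye. A sample only counts (and is only stored) if
its raw position is on or near the screen (10% margin): a participant
looking far off-screen produces no usable calibration data even if the
tracker still reports valid positions. Calibration data stores *raw*
positions; the reported stream is the active calibration applied per
eye, with the identity (default calibration) for uncalibrated eyes —
so "what the tracker reports" changes the moment a calibration is
computed or a snapshot is loaded. Enqueueing during active collection
is permitted and queues behind it.

## The NHP procedure

Defaults follow the procedure's stated constants: ~30 s of attracted
attention, shrink to a 300 × 300 px video, two calibration locations
(placed at (0.3, 0.5) and (0.7, 0.5); the exact default positions are
not dictated), dwell criterion of one third of the vertical screen size
around the video center for at least 500 ms of continuous qualifying
gaze, and a 2 × 4 validation grid (evenly spread: columns at
(2c+1)/8, rows at (2r+1)/4). Open details were resolved as follows:

* **"Watched sufficiently long"** is implemented as *cumulative* watched
  time (default 30 s), so lapses pause rather than restart the phase.
  "Watched" during the full-screen stage means gaze anywhere on-screen.
* **Shrink** is linear in size over a configurable 10 s of watched time,
  advancing only on ticks with gaze on the (current) video rectangle;
  the exact trajectory and duration are not specified anywhere, so both
  are configuration.
* **Dwell timer** resets on a non-qualifying gaze sample; up to one
  consecutive tick with *no* gaze (blink robustness) is tolerated
  without resetting, but does not advance the timer.
* **Failure/retry**: a failed calibration triggers `discard_all` and
  recollection from the first point; retries are unlimited by default
  (`max_retries` available). A successful calibration switches auto
  mode off; re-enabling it (operator confirmation) starts validation,
  whose collection windows equal the calibration ones.
* **Reward** is active exactly while smoothed gaze is inside the video
  rectangle — never for on-screen gaze elsewhere — and a manual command
  pulses it unconditionally.

The adult demo's arc AOIs are annular sectors centered on the screen
center: inner/outer radii at 0.5× and 1.5× the target eccentricity and
each sector spanning the angular third containing its target (closed
regions, boundaries included). The published figure shows arcs but no
dimensions; all of this is configurable.

## Synthetic participant

The simulator emulates what the procedures need from a participant and
a tracker: stimulus-following with lognormal orienting latency (median
250 ms), isotropic Gaussian fixation noise in angular space (default
0.5°/axis/eye) projected to the screen through the viewing geometry,
optional slow drift, blinks (default 10/min, ~150 ms, both eyes
invalid), attention lapses that move gaze off-screen (default 2/min,
~1.5 s), an optional interocular offset, and a per-eye ground-truth
raw-gaze distortion. Noise is applied in angular space because data
quality is reported in degrees. All randomness flows from one seeded
generator in a fixed per-tick order, so identical seed + configuration
give bitwise-identical streams, logs and artifacts.

What it deliberately does *not* model: saccade dynamics and the main
sequence, pupil-size artifacts, head movement and slippage, luminance-
dependent noise, or any video content effects on attention. Passing
closed-loop tests therefore demonstrate the *procedure's* logic and the
calibration model's recovery properties under known ground truth — not
that a real animal would produce these numbers.

## Problem sizes and numerical choices

The test suite runs full three-phase sessions at 60 Hz (a completed
session is ~3,500–4,500 ticks); the parameter-recovery study uses 100
seeded closed-loop runs with a similarity-family ground-truth distortion
of ≈3° mean offset and 0.5° noise, reporting the mean pre- and
post-calibration validation accuracy. Metric-oracle checks use 10,000
samples for distributional statements and exact brute-force
recomputation on small random sets. Timestamps are stream milliseconds
(floats); dwell elapsed time is measured from the first qualifying
filtered sample, so at 60 Hz the 500 ms criterion fires exactly 30
inter-sample intervals after onset. Ties and boundaries: the dwell
distance criterion is strict (`< ⅓·height`), rectangle and AOI
membership are closed (boundaries inside).

## Known limitations

* The calibration stand-in is not the (proprietary) fit of any real
  tracker; residual-bound failure is a proxy criterion.
* Quality metrics use the nominal viewing distance unless per-sample
  eye origins are supplied; both conventions exist in the field.
* The simulator's attention model is memoryless; real participants
  satiate and fatigue within sessions.
* Replay mode treats a recorded log as the reported stream; calibration
  fitting on replayed data is not meaningful because raw positions are
  unknown.
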