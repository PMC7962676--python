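# Methods

## Detection model

Microsaccades and saccades are detected with a two-dimensional
velocity-threshold test. Velocity is a moving-average central difference
over an odd window of `2m+1` samples,

    v_n = Σ_{k=1..m} (x_{n+k} − x_{n−k}) / (2 Δt Σ_{k=1..m} k),

chosen because the window size is an exposed parameter: the weighted form
reduces exactly to the classical 5-sample stencil at `m = 2`, is exact for
affine trajectories at every window size, and attenuates white sensor noise
as the window grows. Velocities are *masked* (left undefined) wherever the
stencil would touch a trace edge or an invalid sample; no interpolation
across gaps is attempted, reflecting distrust of data adjacent to dropouts.

The per-axis velocity dispersion is the median-based estimator
`σ = sqrt(median(v²) − median(v)²)`, insensitive to the rare fast events it
is used to find. Note this estimator is *not* invariant under adding a
constant to all velocities (e.g. shifting {−2,−1,0,1,2} by +10 drives it to
zero); it behaves as intended because ocular velocity during fixation has
median ≈ 0. It is exactly linear under positive rescaling. A dispersion
below 10⁻¹⁰ °/s on either axis raises a degenerate-signal error: constant or
duplicated position data cannot support a threshold. At least 10 defined
velocity samples are required for an estimate; in per-fixation scope,
fixations too short (or locally flat) for a local estimate simply yield no
events, while the default pools all fixation samples of a trial for one
stable estimate per trial (a per-fixation option exists because published
studies differ on this point).

A sample is super-threshold when `(v_x/(λσ_x))² + (v_y/(λσ_y))² > 1`
(strict, so boundary contact does not trigger). Maximal runs of
super-threshold samples are computed over the whole masked trace — runs
never bridge masked samples — and a run becomes a candidate microsaccade
only if it lasts at least the minimum duration and lies entirely inside a
fixation span (a run straddling a fixation boundary is discarded, not
clipped: a fragment of a larger movement is not a microsaccade; the same
rule applies at the ignore windows below).

Candidates are then pruned, in order:

1. **Fixation-edge guards** — candidates overlapping the first
   `ignore_fix_start_ms` (default 20 ms) or last `ignore_fix_end_ms`
   (default 0) of the fixation are dropped. The head guard is the glissade
   control: post-saccadic over/undershoots sit at fixation onset and mimic
   microsaccades.
2. **Missing-data guard** — candidates within `ignore_around_missing_ms`
   of a gap are dropped (default 0; the velocity mask already quarantines
   the window-width neighbourhood of every gap).
3. **Kinematic bounds** — min/max duration, amplitude and peak velocity
   (defaults: min duration 6 ms, max amplitude 1°, others off).
4. **Minimum inter-saccadic interval** — a left-to-right scan drops any
   event starting sooner than `min_isi_ms` (default 20 ms) after the
   previous *kept* event's offset; dropping (rather than merging) matches
   the intent of suppressing overshoot artifacts.

Event kinematics: displacement `(dx, dy)` and direction from the first and
last event samples (0° = rightward, counter-clockwise positive after
flipping the downward screen-y axis, so up on screen = 90°); amplitude from
sign-carrying coordinate ranges `amp_c = sign(argmax − argmin)·(max − min)`,
so `hypot(amp_x, amp_y)` is never below the displacement norm; peak velocity
is the maximum sample speed in the event.

**Binocular mode** (default) detects monocularly in both eyes and keeps only
events with ≥ 1 sample of temporal overlap in both, pairing greedily by
largest overlap (ties: earlier right-eye event) with each monocular event
used at most once; the reported interval is the union and headline
kinematics are the mean of the two eyes. Greedy pairing is not globally
optimal on adversarial overlap chains, but on real binocular data overlaps
are essentially one-to-one; the mean (rather than a stronger-eye rule) was
chosen for symmetry. Binocular agreement suppresses mono-ocular noise
transients at the cost of missing genuinely monocular events.

**Saccade filter and fixations.** The identical pipeline runs over the whole
trial with saccade defaults (λ = 8, min duration 3 ms, window 9, min
amplitude 1°, min ISI 50 ms); the 1° amplitude floor suppresses fixational
events. Fixations are the complement of the detected saccades minus
missing-data gaps, including the leading and trailing intervals; intervals
shorter than one velocity window are discarded; centroids are means of the
valid samples. Precomputed fixations (e.g. an eye tracker's) can be
substituted anywhere the derived ones are used.

## Units and geometry

Detection operates in visual degrees. Pixel data is converted per axis about
the screen centre, `θ = atan((p − c)·mm_per_px / distance_mm)`, which
requires viewing distance and screen pixel/physical dimensions. I/O never
converts units silently; the unit tag travels with the trace. Time is
represented internally as sample index / rate (event intervals are half-open
`[onset, offset)` in 0-based sample indices), which makes file round-trips
exact and avoids accumulated float drift.

## Synthetic gaze generator

The simulator produces labeled trials containing every phenomenon the
detector must face: fixational drift (Gaussian random walk, step SD
10⁻³ °/sample), saccades between fixation centres, injected microsaccades,
post-saccadic glissades, sensor dropouts, white sensor noise (added last),
and binocular recording as one shared signal plus independent per-eye noise.
All rapid movements use raised-cosine velocity profiles, whose closed form
ties peak velocity to amplitude and duration (`V_peak = 2A/T`); microsaccade
durations are derived from the main-sequence law `V_peak = k·A^p`
(`T = 2A^{1−p}/k`, clipped to the configured duration range), so simulated
events land on a controlled main sequence whose exponent analyses should
recover. Glissades are realized as a partial return (default 5 %) of a
deliberately overshot saccade, starting exactly at the saccade offset, i.e.
at the start of the following fixation — which is precisely why they
contaminate the first bins of temporal-position histograms when no
fixation-head guard is used.

Defaults describe a plausible 500 Hz free-viewing recording: fixations
0.8–2.0 s, saccades 2–8° within a ±10° field, microsaccades at 1.5/s of
fixation with amplitudes 0.1–0.8° and durations 6–30 ms, main-sequence gain
100 °/s at 1° with exponent 0.9, glissades after half of all saccades,
dropouts at 0.05/s of 40–150 ms, noise 0.01° RMS (EyeLink-class).
Microsaccades are placed ≥ 100 ms after fixation onset and ≥ 150 ms apart,
mirroring the post-saccadic suppression of real rate profiles; dropouts are
placed clear of true events so ground-truth labels stay meaningful.

Randomness is split into fixed per-phenomenon substreams spawned from the
single seed (layout, drift, microsaccades, glissades, dropouts, per-eye
noise), so toggling one phenomenon leaves every other bit-identical — the
property that makes controlled contrasts (e.g. glissades on/off) exact.

What the simulator does **not** emulate: physiological tremor spectra,
saccadic curvature and dynamic overshoot waveforms, pink/drift-correlated
noise, blink artefacts with partial occlusion, vergence differences between
the eyes, or pupil-size coupling. Passing tests therefore demonstrate
correctness of the *pipeline mechanics* under realistic magnitudes, not
detector performance on any particular eye tracker's noise process.

## Analytics

Directions aggregate into rose histograms over half-open sectors
partitioning [0°, 360°) (12 bins by default), with circular mean
`atan2(Σsin, Σcos)` and circular SD `sqrt(−2 ln R)` (R = mean resultant
length), the standard directional-statistics definition; both are flagged
undefined on empty input. Per-condition counts always sum to the totals.

"Rotation toward the next fixation" subtracts, from each event's direction,
the direction of the vector between its fixation's centroid and the next
fixation's centroid; 0° then means "toward the upcoming fixation". Events in
a trial's last fixation have no successor and are excluded (the exclusion
count is reported). These relative angles are invariant under global
rotation of screen coordinates. Coincident centroids raise an error rather
than returning an arbitrary direction.

Temporal-position histograms count event onsets in 40 ms bins from fixation
onset — the diagnostic view for glissade contamination (first-bin excess).
Main-sequence output is the raw (amplitude, peak velocity) pair list for
log-log plotting; no fit is imposed, and non-positive values (impossible on
a log scale) are excluded with a count.

Summary statistics exist at fixation/trial/participant/condition (and
participant × condition) level. Aggregation above trial level **pools raw
events** — a condition-level mean is the mean over all pooled events, not a
mean of participant means — because pooling keeps the published
"recompute-from-raw-events" identity exact; a per-participant-mean view can
be built from the participant level if sampling-unit weighting is wanted.
Rates are normalised by total *fixation* time (detection is
fixation-scoped), and the inter-saccadic-interval statistics use
onset-to-onset gaps between consecutive microsaccades within a fixation.

## File formats

Trial files are self-describing tab-separated text: a header block
(format-version line, participant, rate, unit, optional geometry) followed
by per-trial blocks of typed rows — `S` samples (timestamps printed at
nanosecond precision), `F` fixations, `M` microsaccades (with kinematic
columns), `E` event markers. Coordinates are written with shortest
round-trip float formatting and intervals as integer sample indices, so
write → read is bit-exact; overlapping same-class events are refused at
write time. Condition files are two-column TSV (duplicate ids rejected by
name; unknown ids rejected when joined onto trials). Aggregated statistics
export as locale-independent CSV with empty markers for undefined means.

## Numerical and testing choices

Millisecond parameters convert to sample counts by ceiling (a 20 ms guard at
500 Hz covers all 10 samples). The elliptic test is strict; ties at the
boundary are sub-threshold. The test suite checks the vectorised pipeline
against an independent, loop-based per-sample reference implementation on
100 seeded synthetic trials spanning eye modes, sigma scopes and guard
settings, and validates circular statistics against an independent circular
statistics library. Problem sizes in tests and in `scripts/acceptance.py`
(5–15 s trials, 8–100 trials per experiment) were chosen so the full suite
runs in seconds while keeping several hundred events per measurement.

## Known limitations

* No smoothing/denoising; preprocessing (blink handling, filtering) is the
  caller's responsibility, by design.
* Square-wave-jerk labeling, clustering- or Bayesian-style detectors are out
  of scope; only the velocity-threshold family is implemented.
* Monocular-only recordings support monocular detection only; binocular
  mode requires both eyes.
* The event-count response to λ is not monotone even though the
  super-threshold *sample set* is: lowering λ merges runs and the ISI guard
  then drops different events. This is a property of the method, not a bug.
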