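# microsacc

Velocity-threshold detection and analysis of **microsaccades** — the small
(< ~1°), fast, involuntary eye movements that occur during fixation — in
high-frequency (≥ 200 Hz) gaze recordings, together with the surrounding
analytics a fixational-eye-movement study needs: saccade/fixation
segmentation, binocular event merging, circular direction statistics,
next-fixation rotation, main-sequence data, multi-level summaries, plain-text
import/export, and a fully seeded synthetic-gaze simulator with ground-truth
labels so every component can be validated without external recordings.

It is aimed at visual-neuroscience and eye-tracking researchers who need a
scriptable, reproducible alternative to point-and-click event filters, and at
anyone who wants to study how detection *parameters* change what counts as a
microsaccade.

## The detector

Per eye, sample velocities are estimated with a moving-average
central-difference stencil (window 2m+1 samples):

    v_n = Σ_{k=1..m} (x_{n+k} − x_{n−k}) / (2 Δt Σ_{k=1..m} k)

which for the common 5-sample window reduces to
`v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) / (6 Δt)` and is exact on
linear motion. A robust, median-based dispersion

    σ = sqrt( median(v²) − median(v)² )

per axis defines an elliptic threshold scaled by a free multiplier λ; a
sample is super-threshold when

    (v_x / (λ σ_x))² + (v_y / (λ σ_y))² > 1 .

Maximal super-threshold runs of at least the minimum duration become
candidate events, which are then pruned by the extended constraints exposed
as parameters: min/max duration, amplitude and peak velocity, a guard window
at fixation start/end (to exclude post-saccadic **glissades**), a guard band
around missing data, a minimum inter-saccadic interval (to exclude
overshoots), and monocular vs **binocular** agreement (an event must overlap
in both eyes). Defaults: λ = 5, min duration 6 ms, window 5 samples, max
amplitude 1°, min ISI 20 ms, first 20 ms of each fixation ignored, binocular.

The same pipeline with different defaults (λ = 8, min duration 3 ms, window
9 samples, min amplitude 1°, min ISI 50 ms) acts as a saccade filter;
**fixations are the intervals between detected saccades**, and microsaccades
are detected strictly inside fixations.

Event kinematics follow the field conventions: amplitude from sign-carrying
coordinate ranges (`amp = hypot(Δx_range, Δy_range)`), direction from the
start→end displacement (0° = rightward, 90° = up on screen), peak velocity
as the maximum sample speed.

## Worked example

```python
from microsacc import (SimConfig, simulate_trial, detect_trial,
                       match_events, summary_statistics)

cfg = SimConfig(trial_s=10.0)            # 500 Hz binocular free-viewing trial
trial, truth = simulate_trial(cfg, seed=7)
fixations, events = detect_trial(trial)  # saccade filter -> microsaccade filter

stats = summary_statistics([(trial, fixations, events)], level="trial")[0]
res = match_events(events, truth.microsaccades, tol_ms=4.0, rate_hz=cfg.rate_hz)

print(f"fixations:            {stats.fixation_count}")
print(f"microsaccades:        {stats.ms_count}")
print(f"rate:                 {stats.ms_per_second:.2f} per s of fixation")
print(f"amplitude:            {stats.ms_amplitude_mean_deg:.3f} +/- {stats.ms_amplitude_sd_deg:.3f} deg")
print(f"peak velocity:        {stats.ms_peak_velocity_mean_degs:.1f} +/- {stats.ms_peak_velocity_sd_degs:.1f} deg/s")
print(f"precision / recall:   {res.precision:.2f} / {res.recall:.2f}")
```

prints

```
fixations:            8
microsaccades:        9
rate:                 0.93 per s of fixation
amplitude:            0.356 +/- 0.232 deg
peak velocity:        35.1 +/- 20.2 deg/s
precision / recall:   1.00 / 1.00
```

i.e. on this simulated trial the default filter segments 8 fixations,
recovers all 9 injected microsaccades with no false alarms (onsets within
4 ms of ground truth), and reports their kinematics: mean amplitude ~0.36°
with peak velocities on the main sequence (~35°/s at that amplitude).

The same pipeline is scriptable from a shell:

```
microsacc simulate --out runs/sim --participants 2 --trials 3 --seed 1
microsacc detect   --input runs/sim/p01.tsv --out runs/det --lam 5
microsacc stats    --input runs/det/p01_t01.tsv --out runs/stats --level overall
microsacc sweep    --input runs/sim/p01.tsv --out runs/sweep \
                   --param lam --values 3,5,8,10
```

Every command writes `resolved_config.txt` next to its outputs, so a run is
reproducible from its output directory alone.

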