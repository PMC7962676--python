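"""Velocity-threshold detection of microsaccades and saccades.

The detector marks a sample as super-threshold when its velocity lies outside
the ellipse

    (vx / (lam * sigma_x))**2 + (vy / (lam * sigma_y))**2 > 1

where ``sigma`` is the median-based dispersion of the velocity signal and
``lam`` a free multiplier.  Maximal runs of super-threshold samples that last
at least the minimum duration become candidate events; the extended
constraints (fixation-edge guard windows, missing-data guard, duration /
amplitude / peak-velocity bounds, minimum inter-saccadic interval) then prune
the candidates.  Saccade detection runs the identical pipeline over the whole
trial with its own defaults; fixations are the intervals between saccades.

Binocular mode detects monocularly in both eyes and keeps only events with
temporal overlap in both, which suppresses mono-ocular noise transients.
"""

from __future__ import annotations

import numpy as np

from .core import (
    DegenerateSignalError,
    DetectorParams,
    Fixation,
    GazeEvent,
    GazeTrace,
    SaccadeFilterParams,
    Trial,
    ValidationError,
    mask_to_intervals,
)
from .kinematics import (
    MIN_SIGMA_SAMPLES,
    VelocitySeries,
    estimate_velocity,
    robust_sigma,
)

__all__ = [
    "threshold_candidates",
    "event_kinematics",
    "apply_constraints",
    "merge_binocular",
    "detect_microsaccades",
    "detect_saccades",
    "detect_trial",
    "derive_fixations",
    "average_eyes",
    "direction_degrees",
]

Interval = tuple[int, int]


def direction_degrees(dx: float, dy: float) -> float:
    """Direction of a screen-coordinate displacement, 0 = right, 90 = up.

    Screen y grows downward, so the y component is negated before ``atan2``.
    """
    ang = np.degrees(np.arctan2(-dy, dx)) % 360.0
    return float(ang)


def threshold_candidates(
    vel: VelocitySeries,
    sigma: tuple[float, float],
    lam: float,
    min_dur_samples: int,
) -> list[Interval]:
    """Maximal super-threshold runs of at least ``min_dur_samples`` samples.

    The ellipse test is strict (``> 1``); a sample exactly on the threshold
    boundary is sub-threshold.  Runs never bridge masked samples.
    """
    sx, sy = sigma
    with np.errstate(invalid="ignore"):
        crit = (vel.vx / (lam * sx)) ** 2 + (vel.vy / (lam * sy)) ** 2
    above = vel.defined_mask & (crit > 1.0)
    return [iv for iv in mask_to_intervals(above) if iv[1] - iv[0] >= min_dur_samples]


def event_kinematics(
    trace: GazeTrace,
    vel: VelocitySeries,
    onset: int,
    offset: int,
    kind: str,
) -> GazeEvent:
    """Kinematic properties of one event interval ``[onset, offset)``.

    Displacement ``(dx, dy)`` runs from the first to the last sample of the
    event.  The amplitude components are sign-carrying coordinate ranges:
    ``amp_x = sign(argmax - argmin) * (max(x) - min(x))``, so the scalar
    amplitude ``hypot(amp_x, amp_y)`` captures the full excursion even when
    the eye returns partway (it is never below the displacement norm).
    """
    xs = trace.x[onset:offset]
    ys = trace.y[onset:offset]
    dx = float(xs[-1] - xs[0])
    dy = float(ys[-1] - ys[0])

    def signed_range(c: np.ndarray) -> float:
        i_min = int(np.argmin(c))
        i_max = int(np.argmax(c))
        rng = float(c[i_max] - c[i_min])
        return rng if i_max >= i_min else -rng

    amp_x = signed_range(xs)
    amp_y = signed_range(ys)
    pv = float(np.nanmax(vel.speed[onset:offset]))
    return GazeEvent(
        kind=kind,
        eye=trace.eye,
        onset_idx=int(onset),
        offset_idx=int(offset),
        rate_hz=trace.rate_hz,
        dx=dx,
        dy=dy,
        amp_x=amp_x,
        amp_y=amp_y,
        amplitude=float(np.hypot(amp_x, amp_y)),
        peak_velocity=pv,
        direction_deg=direction_degrees(dx, dy),
    )


def _ms_to_samples(ms: float, rate_hz: float) -> int:
    # ceil so a guard of e.g. 20 ms at 500 Hz covers the full 10 samples
    return int(np.ceil(ms * rate_hz / 1000.0 - 1e-9))


def apply_constraints(
    candidates: list[Interval],
    trace: GazeTrace,
    vel: VelocitySeries,
    params: DetectorParams | SaccadeFilterParams,
    kind: str,
    fixation: Fixation | None = None,
) -> list[GazeEvent]:
    """Filter candidate intervals through the extended constraints.

    Order of application:

    1. drop candidates overlapping the ignored head/tail of the fixation
       (glissade guard) — overlap means drop, never trim;
    2. drop candidates within the missing-data guard band of any gap;
    3. compute kinematics and drop events violating duration, amplitude or
       peak-velocity bounds;
    4. left-to-right scan dropping any event whose onset follows the previous
       kept event's offset by less than the minimum inter-saccadic interval
       (overshoot guard).
    """
    rate = trace.rate_hz
    kept: list[Interval] = []
    lo = fixation.onset_idx if fixation is not None else 0
    hi = fixation.offset_idx if fixation is not None else len(trace)
    g_start = _ms_to_samples(params.ignore_fix_start_ms, rate) if fixation is not None else 0
    g_end = _ms_to_samples(params.ignore_fix_end_ms, rate) if fixation is not None else 0
    guard_miss = _ms_to_samples(params.ignore_around_missing_ms, rate)
    gaps = trace.missing_ranges

    for onset, offset in candidates:
        if onset < lo + g_start:  # touches the ignored fixation head
            continue
        if offset > hi - g_end:  # touches the ignored fixation tail
            continue
        # guard band around gaps: event must not come within guard_miss
        # samples of any missing range
        if any(onset < ge + guard_miss and offset > gs - guard_miss for gs, ge in gaps):
            continue
        kept.append((onset, offset))

    events: list[GazeEvent] = []
    for onset, offset in kept:
        ev = event_kinematics(trace, vel, onset, offset, kind)
        if params.min_dur_ms is not None and ev.duration_ms < params.min_dur_ms:
            continue
        if params.max_dur_ms is not None and ev.duration_ms > params.max_dur_ms:
            continue
        if params.min_amp_deg is not None and ev.amplitude < params.min_amp_deg:
            continue
        if params.max_amp_deg is not None and ev.amplitude > params.max_amp_deg:
            continue
        if params.min_pv_degs is not None and ev.peak_velocity < params.min_pv_degs:
            continue
        if params.max_pv_degs is not None and ev.peak_velocity > params.max_pv_degs:
            continue
        events.append(ev)

    min_isi = _ms_to_samples(params.min_isi_ms, rate)
    out: list[GazeEvent] = []
    for ev in events:
        if out and ev.onset_idx - out[-1].offset_idx < min_isi:
            continue
        out.append(ev)
    return out


def merge_binocular(
    left_events: list[GazeEvent], right_events: list[GazeEvent]
) -> list[GazeEvent]:
    """Pair left/right events with temporal overlap into binocular events.

    Each monocular event joins at most one pair; pairs are chosen greedily by
    largest overlap (ties favour the earlier right event).  The binocular
    interval is the union of the pair; headline kinematics are the mean of
    the two eyes, and the per-eye events remain reachable via ``partner``.
    """
    pairs: list[tuple[int, int, int]] = []  # (-overlap, li, ri)
    for li, le in enumerate(left_events):
        for ri, re in enumerate(right_events):
            ov = min(le.offset_idx, re.offset_idx) - max(le.onset_idx, re.onset_idx)
            if ov >= 1:
                pairs.append((-ov, li, ri))
    pairs.sort()  # largest overlap first; ties -> smaller li, then earlier ri
    used_l: set[int] = set()
    used_r: set[int] = set()
    merged: list[GazeEvent] = []
    for neg_ov, li, ri in pairs:
        if li in used_l or ri in used_r:
            continue
        used_l.add(li)
        used_r.add(ri)
        le, re = left_events[li], right_events[ri]
        onset = min(le.onset_idx, re.onset_idx)
        offset = max(le.offset_idx, re.offset_idx)
        dx = (le.dx + re.dx) / 2.0
        dy = (le.dy + re.dy) / 2.0
        amp_x = (le.amp_x + re.amp_x) / 2.0
        amp_y = (le.amp_y + re.amp_y) / 2.0
        ev = GazeEvent(
            kind=le.kind,
            eye="binocular",
            onset_idx=onset,
            offset_idx=offset,
            rate_hz=le.rate_hz,
            dx=dx,
            dy=dy,
            amp_x=amp_x,
            amp_y=amp_y,
            amplitude=(le.amplitude + re.amplitude) / 2.0,
            peak_velocity=(le.peak_velocity + re.peak_velocity) / 2.0,
            direction_deg=direction_degrees(dx, dy),
            fixation_id=le.fixation_id,
            partner=re,
        )
        merged.append(ev)
    merged.sort(key=lambda e: e.onset_idx)
    return merged


def _fixation_scope_mask(n: int, fixations: list[Fixation]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for f in fixations:
        mask[f.onset_idx : f.offset_idx] = True
    return mask


def _detect_monocular(
    trace: GazeTrace,
    fixations: list[Fixation],
    params: DetectorParams,
) -> list[GazeEvent]:
    vel = estimate_velocity(trace, params.vel_window)
    min_dur = max(_ms_to_samples(params.min_dur_ms or 0.0, trace.rate_hz), 1)
    events: list[GazeEvent] = []
    if params.sigma_scope == "trial":
        scope = _fixation_scope_mask(len(trace), fixations)
        pooled_sigma = robust_sigma(vel, scope)
    for fix in fixations:
        fmask = np.zeros(len(trace), dtype=bool)
        fmask[fix.onset_idx : fix.offset_idx] = True
        if params.sigma_scope == "fixation":
            # a fixation too short to estimate a local threshold yields
            # no events (cannot be tested against an undefined dispersion)
            if np.count_nonzero(vel.defined_mask & fmask) < MIN_SIGMA_SAMPLES:
                continue
            try:
                sigma = robust_sigma(vel, fmask)
            except DegenerateSignalError:
                # locally flat signal: no meaningful threshold here
                continue
        else:
            sigma = pooled_sigma
        cands = threshold_candidates(vel, sigma, params.lam, min_dur)
        cands = [
            (a, b) for a, b in cands if a >= fix.onset_idx and b <= fix.offset_idx
        ]
        evs = apply_constraints(cands, trace, vel, params, "microsaccade", fix)
        for ev in evs:
            ev.fixation_id = fix.id
            ev.t_in_fixation_ms = (ev.onset_idx - fix.onset_idx) / trace.rate_hz * 1000.0
        events.extend(evs)
    return events


def detect_microsaccades(
    trial: Trial,
    fixations: list[Fixation],
    params: DetectorParams = DetectorParams(),
) -> list[GazeEvent]:
    """Detect microsaccades within fixations of a trial.

    In ``binocular`` eye mode both eyes are detected monocularly and merged;
    otherwise the selected trace ("left", "right" or "averaged") is used
    directly.  Traces must be in visual degrees.

    Returned events are sorted by onset and carry their owning fixation id
    and onset latency within the fixation.
    """
    for tr in trial.traces.values():
        if tr.unit != "deg":
            raise ValidationError(
                "detection requires traces in visual degrees; convert pixel "
                "data with kinematics.pixels_to_degrees first"
            )
    if params.eye_mode == "binocular":
        left = _detect_monocular(trial.trace("left"), fixations, params)
        right = _detect_monocular(trial.trace("right"), fixations, params)
        events = merge_binocular(left, right)
        # fixation ownership follows the left partner (both eyes share the
        # fixation segmentation)
        fix_by_id = {f.id: f for f in fixations}
        for ev in events:
            fix = fix_by_id[ev.fixation_id]
            ev.t_in_fixation_ms = (
                (ev.onset_idx - fix.onset_idx) / ev.rate_hz * 1000.0
            )
    else:
        events = _detect_monocular(trial.trace(params.eye_mode), fixations, params)
    events.sort(key=lambda e: e.onset_idx)
    for f in fixations:
        f.microsaccade_ids = [
            i for i, e in enumerate(events) if e.fixation_id == f.id
        ]
    return events


def detect_saccades(
    trace: GazeTrace, params: SaccadeFilterParams = SaccadeFilterParams()
) -> list[GazeEvent]:
    """Detect saccades over a whole-trial trace (no fixation windows).

    The minimum-amplitude default of 1 deg suppresses fixational events.
    """
    if trace.unit != "deg":
        raise ValidationError("saccade detection requires a trace in visual degrees")
    vel = estimate_velocity(trace, params.vel_window)
    sigma = robust_sigma(vel)
    min_dur = max(_ms_to_samples(params.min_dur_ms or 0.0, trace.rate_hz), 1)
    cands = threshold_candidates(vel, sigma, params.lam, min_dur)
    return apply_constraints(cands, trace, vel, params, "saccade", None)


def derive_fixations(
    trace: GazeTrace,
    saccades: list[GazeEvent],
    min_samples: int | None = None,
) -> list[Fixation]:
    """Fixations as the complement of saccades, minus missing-data gaps.

    Includes the leading interval (trace start to first saccade) and the
    trailing one.  Intervals shorter than ``min_samples`` (default: one
    velocity window of the standard microsaccade filter, 5 samples) are
    dropped.  Centroids are means of the valid samples in the span.
    """
    n = len(trace)
    occupied = np.zeros(n, dtype=bool)
    for s in saccades:
        occupied[s.onset_idx : s.offset_idx] = True
    occupied |= ~trace.valid
    free = mask_to_intervals(~occupied)
    if min_samples is None:
        min_samples = 5
    fixations: list[Fixation] = []
    for a, b in free:
        if b - a < min_samples:
            continue
        cx = float(np.nanmean(trace.x[a:b]))
        cy = float(np.nanmean(trace.y[a:b]))
        fixations.append(
            Fixation(
                id=len(fixations),
                onset_idx=a,
                offset_idx=b,
                rate_hz=trace.rate_hz,
                centroid=(cx, cy),
            )
        )
    return fixations


def detect_trial(
    trial: Trial,
    params: DetectorParams = DetectorParams(),
    sacc_params: SaccadeFilterParams = SaccadeFilterParams(),
    fixations: list[Fixation] | None = None,
) -> tuple[list[Fixation], list[GazeEvent]]:
    """Full per-trial pipeline: fixations (via the saccade filter) then
    microsaccades within them.

    ``fixations`` short-circuits the saccade filter (precomputed fixations,
    e.g. from an eye tracker or a trial file).  The trace used for saccade
    detection is the eye-mode trace when monocular, otherwise the averaged
    trace (falling back to the left eye if no average is present).
    """
    if fixations is None:
        if params.eye_mode in ("left", "right", "averaged"):
            fix_eye = params.eye_mode
        else:
            fix_eye = "averaged" if "averaged" in trial.traces else "left"
        saccades = detect_saccades(trial.trace(fix_eye), sacc_params)
        fixations = derive_fixations(
            trial.trace(fix_eye), saccades, min_samples=params.vel_window
        )
    events = detect_microsaccades(trial, fixations, params)
    return fixations, events


def average_eyes(left: GazeTrace, right: GazeTrace) -> GazeTrace:
    """Sample-wise mean of both eyes; invalid where either eye is invalid."""
    if len(left) != len(right):
        raise ValidationError(
            f"eye traces differ in length: {len(left)} vs {len(right)}"
        )
    if left.rate_hz != right.rate_hz:
        raise ValidationError("eye traces differ in sampling rate")
    if left.unit != right.unit:
        raise ValidationError("eye traces differ in unit")
    valid = left.valid & right.valid
    x = (left.x + right.x) / 2.0
    y = (left.y + right.y) / 2.0
    return GazeTrace(
        eye="averaged", x=x, y=y, valid=valid, rate_hz=left.rate_hz, unit=left.unit
    )
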