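"""Independent naive reference implementation of the detection pipeline.

Deliberately written with explicit Python loops and per-sample scans, sharing
no code with the package, so it can serve as an oracle for the vectorised
implementation.  Semantics mirror the documented pipeline:

velocity stencil -> median-based sigma (pooled over fixation samples) ->
per-sample elliptic threshold scan -> maximal runs -> minimum duration ->
fixation-edge guards (overlap = drop) -> missing-data guard -> kinematic
bounds -> left-to-right minimum-ISI scan -> optional binocular pairing.
"""

from __future__ import annotations

import math


def ms_to_samples(ms: float, rate: float) -> int:
    return math.ceil(ms * rate / 1000.0 - 1e-9)


def velocity(xs, ys, valid, rate: float, window: int):
    n = len(xs)
    m = (window - 1) // 2
    denom = 2.0 * sum(range(1, m + 1)) / rate
    vx = [math.nan] * n
    vy = [math.nan] * n
    defined = [False] * n
    for i in range(n):
        if i - m < 0 or i + m >= n:
            continue
        if not all(valid[j] for j in range(i - m, i + m + 1)):
            continue
        sx = sum(xs[i + k] - xs[i - k] for k in range(1, m + 1))
        sy = sum(ys[i + k] - ys[i - k] for k in range(1, m + 1))
        vx[i] = sx / denom
        vy[i] = sy / denom
        defined[i] = True
    return vx, vy, defined


def _median(vals):
    s = sorted(vals)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def sigma(vx, vy, defined, scope):
    """scope: iterable of sample indices."""
    out = []
    for comp in (vx, vy):
        vals = [comp[i] for i in scope if defined[i]]
        med = _median(vals)
        med2 = _median([v * v for v in vals])
        out.append(math.sqrt(max(med2 - med * med, 0.0)))
    return out[0], out[1]


def runs_above(vx, vy, defined, sx, sy, lam):
    n = len(vx)
    above = [
        defined[i] and (vx[i] / (lam * sx)) ** 2 + (vy[i] / (lam * sy)) ** 2 > 1.0
        for i in range(n)
    ]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def event_props(xs, ys, vx, vy, onset, offset, rate):
    seg_x = xs[onset:offset]
    seg_y = ys[onset:offset]
    ix_min = seg_x.index(min(seg_x))
    ix_max = seg_x.index(max(seg_x))
    iy_min = seg_y.index(min(seg_y))
    iy_max = seg_y.index(max(seg_y))
    ax = (max(seg_x) - min(seg_x)) * (1 if ix_max >= ix_min else -1)
    ay = (max(seg_y) - min(seg_y)) * (1 if iy_max >= iy_min else -1)
    amp = math.hypot(ax, ay)
    pv = max(
        math.hypot(vx[i], vy[i])
        for i in range(onset, offset)
        if not math.isnan(vx[i])
    )
    dur_ms = (offset - onset) / rate * 1000.0
    return amp, pv, dur_ms


def missing_ranges(valid):
    out = []
    i = 0
    n = len(valid)
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_in_fixation(xs, ys, valid, vx, vy, defined, sx, sy, fix, p, rate):
    """Candidate intervals surviving all constraints within one fixation.

    ``fix`` is (onset, offset); ``p`` a DetectorParams-like object.
    Returns a list of (onset, offset) kept events.
    """
    lo, hi = fix
    min_dur = max(ms_to_samples(p.min_dur_ms or 0.0, rate), 1)
    cands = [
        (a, b)
        for a, b in runs_above(vx, vy, defined, sx, sy, p.lam)
        if b - a >= min_dur and a >= lo and b <= hi
    ]
    g0 = ms_to_samples(p.ignore_fix_start_ms, rate)
    g1 = ms_to_samples(p.ignore_fix_end_ms, rate)
    gm = ms_to_samples(p.ignore_around_missing_ms, rate)
    gaps = missing_ranges(valid)
    kept = []
    for a, b in cands:
        if a < lo + g0:
            continue
        if b > hi - g1:
            continue
        if any(a < ge + gm and b > gs - gm for gs, ge in gaps):
            continue
        amp, pv, dur = event_props(xs, ys, vx, vy, a, b, rate)
        if p.min_dur_ms is not None and dur < p.min_dur_ms:
            continue
        if p.max_dur_ms is not None and dur > p.max_dur_ms:
            continue
        if p.min_amp_deg is not None and amp < p.min_amp_deg:
            continue
        if p.max_amp_deg is not None and amp > p.max_amp_deg:
            continue
        if p.min_pv_degs is not None and pv < p.min_pv_degs:
            continue
        if p.max_pv_degs is not None and pv > p.max_pv_degs:
            continue
        kept.append((a, b))
    isi = ms_to_samples(p.min_isi_ms, rate)
    out = []
    for a, b in kept:
        if out and a - out[-1][1] < isi:
            continue
        out.append((a, b))
    return out


def detect_eye(trace_xs, trace_ys, valid, fixations, p, rate):
    """Full monocular pipeline for one eye; fixations as (onset, offset)."""
    vx, vy, defined = velocity(trace_xs, trace_ys, valid, rate, p.vel_window)
    pooled_scope = [i for a, b in fixations for i in range(a, b)]
    events = []
    for fix in fixations:
        if p.sigma_scope == "fixation":
            scope = list(range(fix[0], fix[1]))
            if sum(1 for i in scope if defined[i]) < 10:
                continue  # too short for a local dispersion estimate
        else:
            scope = pooled_scope
        sx, sy = sigma(vx, vy, defined, scope)
        if p.sigma_scope == "fixation" and (sx < 1e-10 or sy < 1e-10):
            continue  # locally flat signal: no meaningful threshold
        events.extend(
            detect_in_fixation(trace_xs, trace_ys, valid, vx, vy, defined,
                               sx, sy, fix, p, rate)
        )
    return events


def merge_binocular_intervals(left, right):
    """Greedy largest-overlap pairing; returns union intervals."""
    pairs = []
    for li, (la, lb) in enumerate(left):
        for ri, (ra, rb) in enumerate(right):
            ov = min(lb, rb) - max(la, ra)
            if ov >= 1:
                pairs.append((-ov, li, ri))
    pairs.sort()
    used_l, used_r, out = set(), set(), []
    for _, li, ri in pairs:
        if li in used_l or ri in used_r:
            continue
        used_l.add(li)
        used_r.add(ri)
        la, lb = left[li]
        ra, rb = right[ri]
        out.append((min(la, ra), max(lb, rb)))
    return sorted(out)


def detect_trial_reference(trial, fixations, params):
    """Intervals of the full pipeline (ints), mirroring detect_microsaccades."""
    rate = trial.rate_hz
    fix_iv = [(f.onset_idx, f.offset_idx) for f in fixations]

    def eye_lists(eye):
        tr = trial.traces[eye]
        return list(tr.x), list(tr.y), list(tr.valid)

    if params.eye_mode == "binocular":
        lx, ly, lv = eye_lists("left")
        rx, ry, rv = eye_lists("right")
        left = detect_eye(lx, ly, lv, fix_iv, params, rate)
        right = detect_eye(rx, ry, rv, fix_iv, params, rate)
        return merge_binocular_intervals(left, right)
    xs, ys, vv = eye_lists(params.eye_mode)
    return sorted(detect_eye(xs, ys, vv, fix_iv, params, rate))
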