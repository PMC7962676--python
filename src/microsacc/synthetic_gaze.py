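"""Seeded synthetic high-frequency gaze traces with ground-truth labels.

The generator emulates, per trial, the phenomena a velocity-threshold
detector must handle:

* fixational drift — a per-sample Gaussian random walk;
* saccades between fixation centres, realised with raised-cosine velocity
  profiles;
* microsaccades injected inside fixations, raised-cosine as well, with
  durations tied to amplitude through a main-sequence law
  ``peak_velocity = gain * amplitude ** exponent`` (a raised-cosine profile
  of amplitude A and duration T has peak velocity exactly ``2 A / T``, so
  choosing ``T = 2 A**(1-p) / k`` realises the law in closed form);
* post-saccadic glissades — a partial return of the saccade's overshoot,
  starting exactly at the saccade offset (the start of the next fixation);
* sensor dropouts (validity gaps) inside fixations;
* sensor noise, added last;
* binocular recording — one shared signal plus independent per-eye noise.

Randomness is split into per-phenomenon substreams spawned from the single
seed, so disabling one phenomenon leaves every other bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GazeEvent, GazeTrace, Trial, ValidationError
from .detection import average_eyes, direction_degrees

__all__ = [
    "SimConfig",
    "TrueEvent",
    "GroundTruth",
    "GenerationError",
    "simulate_trial",
    "simulate_dataset",
    "match_events",
    "MatchResult",
    "write_ground_truth",
    "read_ground_truth",
]


class GenerationError(RuntimeError):
    """The requested event rates/durations cannot be packed into the trial."""


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-trial parameters.

    Durations in seconds or ms as named; amplitudes in visual degrees.
    Defaults describe a free-viewing recording at 500 Hz: fixations of
    0.8-2.0 s separated by 2-8 deg saccades, microsaccades at ~1.5 per
    second of fixation with amplitudes 0.1-0.8 deg, EyeLink-like sensor
    noise (0.01 deg RMS) and slow drift.
    """

    rate_hz: float = 500.0
    trial_s: float = 10.0
    fixation_dur_s: tuple[float, float] = (0.8, 2.0)
    saccade_amp_deg: tuple[float, float] = (2.0, 8.0)
    field_half_extent_deg: float = 10.0
    drift_step_sd_deg: float = 0.001
    noise_sd_deg: float = 0.01
    ms_rate_per_s: float = 1.5
    ms_amp_deg: tuple[float, float] = (0.1, 0.8)
    ms_dur_ms: tuple[float, float] = (6.0, 30.0)
    ms_min_sep_ms: float = 150.0
    ms_margin_start_ms: float = 100.0
    ms_margin_end_ms: float = 50.0
    main_seq_gain: float = 100.0  # deg/s at 1 deg amplitude
    main_seq_exponent: float = 0.9
    glissade_prob: float = 0.5
    glissade_overshoot_frac: float = 0.05
    glissade_dur_ms: tuple[float, float] = (10.0, 30.0)
    dropout_rate_per_s: float = 0.05
    dropout_gap_ms: tuple[float, float] = (40.0, 150.0)
    binocular: bool = True

    def __post_init__(self) -> None:
        if self.rate_hz < 200:
            raise ValidationError("simulated rate must be >= 200 Hz")
        for name in (
            "fixation_dur_s",
            "saccade_amp_deg",
            "ms_amp_deg",
            "ms_dur_ms",
            "glissade_dur_ms",
            "dropout_gap_ms",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be a positive (lo, hi) range")


@dataclass
class TrueEvent:
    """Ground-truth event interval, half-open in sample indices."""

    onset_idx: int
    offset_idx: int
    amplitude: float = float("nan")
    direction_deg: float = float("nan")

    @property
    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx


@dataclass
class GroundTruth:
    """True event inventory of one simulated trial."""

    fixations: list[TrueEvent] = field(default_factory=list)
    saccades: list[TrueEvent] = field(default_factory=list)
    microsaccades: list[TrueEvent] = field(default_factory=list)
    glissades: list[TrueEvent] = field(default_factory=list)
    gaps: list[TrueEvent] = field(default_factory=list)


# fixed substream layout: spawning order defines stream identity, so toggling
# one phenomenon never perturbs another
_STREAMS = ("layout", "drift", "microsaccade", "glissade", "dropout", "noise_l", "noise_r")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _raised_cosine(n: int) -> np.ndarray:
    """Normalised displacement profile of a raised-cosine velocity pulse.

    Returns ``s`` with ``s[0] ~ 0`` and ``s[-1] = 1`` over ``n`` samples;
    the corresponding velocity is ``(1 - cos(2 pi t / T)) / T`` scaled.
    """
    u = np.arange(1, n + 1) / n
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _ms_duration_s(amp: float, cfg: SimConfig) -> float:
    t = 2.0 * amp ** (1.0 - cfg.main_seq_exponent) / cfg.main_seq_gain
    lo, hi = cfg.ms_dur_ms
    return float(np.clip(t, lo / 1000.0, hi / 1000.0))


def simulate_trial(
    config: SimConfig,
    seed: int,
    trial_id: str = "t1",
    participant_id: str = "p1",
) -> tuple[Trial, GroundTruth]:
    """Generate one labeled trial; reproducible given ``(config, seed)``.

    Returns the trial (traces in visual degrees: left/right/averaged when
    binocular, a single right eye otherwise) and its ground truth.
    """
    rng = _rngs(seed)
    rate = config.rate_hz
    dt = 1.0 / rate
    n = int(round(config.trial_s * rate))
    truth = GroundTruth()
    pos = np.zeros((n, 2))

    lay = rng["layout"]
    gli = rng["glissade"]
    i = 0
    p = np.zeros(2)
    pending_glissade: Optional[tuple[np.ndarray, int]] = None  # (return vector, n samples)
    while i < n:
        # ---- fixation segment ----
        nf = int(round(lay.uniform(*config.fixation_dur_s) * rate))
        nf = min(nf, n - i)
        seg = np.empty((nf, 2))
        drift = np.cumsum(
            rng["drift"].normal(0.0, config.drift_step_sd_deg, size=(nf, 2)), axis=0
        )
        seg[:] = p + drift
        fix_start = i

        # glissade return at fixation start (overshoot of the previous saccade)
        if pending_glissade is not None:
            vec, ng = pending_glissade
            ng = min(ng, nf)
            if ng >= 2:
                prof = _raised_cosine(ng)
                seg[:ng] += vec[None, :] * prof[:, None]
                seg[ng:] += vec[None, :]
                truth.glissades.append(
                    TrueEvent(fix_start, fix_start + ng,
                              float(np.hypot(*vec)),
                              direction_degrees(vec[0], vec[1]))
                )
            pending_glissade = None

        # microsaccade injections
        m0 = int(round(config.ms_margin_start_ms / 1000.0 * rate))
        m1 = int(round(config.ms_margin_end_ms / 1000.0 * rate))
        sep = int(round(config.ms_min_sep_ms / 1000.0 * rate))
        usable = nf - m0 - m1
        msr = rng["microsaccade"]
        if usable > 0 and config.ms_rate_per_s > 0:
            want = msr.poisson(config.ms_rate_per_s * usable * dt)
            onsets: list[tuple[int, int]] = []
            for _ in range(want):
                amp = msr.uniform(*config.ms_amp_deg)
                theta = msr.uniform(0.0, 360.0)
                nm = max(int(round(_ms_duration_s(amp, config) * rate)), 2)
                placed = False
                for _attempt in range(30):
                    on = int(msr.integers(m0, max(nf - m1 - nm, m0) + 1))
                    if all(
                        on + nm + sep <= o or o2 + sep <= on for o, o2 in onsets
                    ):
                        placed = True
                        break
                if not placed:
                    continue
                onsets.append((on, on + nm))
                # screen-up positive angle -> negative screen y
                vec = amp * np.array(
                    [np.cos(np.radians(theta)), -np.sin(np.radians(theta))]
                )
                prof = _raised_cosine(nm)
                seg[on : on + nm] += vec[None, :] * prof[:, None]
                seg[on + nm :] += vec[None, :]
                truth.microsaccades.append(
                    TrueEvent(fix_start + on, fix_start + on + nm, amp, theta)
                )
        truth.fixations.append(TrueEvent(fix_start, fix_start + nf))
        p = seg[-1].copy()
        pos[i : i + nf] = seg
        i += nf
        if i >= n:
            break

        # ---- saccade segment ----
        amp = lay.uniform(*config.saccade_amp_deg)
        theta = lay.uniform(0.0, 360.0)
        vec = amp * np.array([np.cos(np.radians(theta)), -np.sin(np.radians(theta))])
        if np.max(np.abs(p + vec)) > config.field_half_extent_deg:
            # re-aim toward the screen centre, with jitter
            back = np.degrees(np.arctan2(-(-p[1]), -p[0]))  # direction to origin
            theta = back + lay.uniform(-30.0, 30.0)
            vec = amp * np.array(
                [np.cos(np.radians(theta)), -np.sin(np.radians(theta))]
            )
        pv = config.main_seq_gain * amp ** config.main_seq_exponent
        ns = max(int(round(2.0 * amp / pv * rate)), 2)
        ns = min(ns, n - i)
        overshoot = (
            config.glissade_overshoot_frac
            if gli.uniform() < config.glissade_prob
            else 0.0
        )
        prof = _raised_cosine(ns)
        full = vec * (1.0 + overshoot)
        pos[i : i + ns] = p + full[None, :] * prof[:, None]
        truth.saccades.append(
            TrueEvent(i, i + ns, amp, theta % 360.0)
        )
        if overshoot > 0.0:
            ng = max(int(round(gli.uniform(*config.glissade_dur_ms) / 1000.0 * rate)), 2)
            pending_glissade = (-vec * overshoot, ng)
        p = p + full
        i += ns

    if not truth.fixations:
        raise GenerationError("trial too short to contain a fixation")

    # ---- dropouts (within fixations, clear of true events) ----
    valid = np.ones(n, dtype=bool)
    drp = rng["dropout"]
    if config.dropout_rate_per_s > 0:
        n_gaps = drp.poisson(config.dropout_rate_per_s * config.trial_s)
        protected = [
            (ev.onset_idx - 10, ev.offset_idx + 10)
            for ev in truth.microsaccades + truth.glissades
        ]
        for _ in range(n_gaps):
            glen = int(round(drp.uniform(*config.dropout_gap_ms) / 1000.0 * rate))
            for _attempt in range(30):
                fix = truth.fixations[int(drp.integers(len(truth.fixations)))]
                if fix.n_samples <= glen + 20:
                    continue
                start = int(
                    drp.integers(fix.onset_idx + 10, fix.offset_idx - glen - 10)
                )
                span = (start, start + glen)
                if any(span[0] < b and span[1] > a for a, b in protected):
                    continue
                valid[span[0] : span[1]] = False
                truth.gaps.append(TrueEvent(span[0], span[1]))
                protected.append((span[0] - 10, span[1] + 10))
                break
    truth.gaps.sort(key=lambda g: g.onset_idx)

    # ---- per-eye noise, added last ----
    def make_trace(eye: str, noise_rng: np.random.Generator) -> GazeTrace:
        noise = noise_rng.normal(0.0, config.noise_sd_deg, size=(n, 2))
        return GazeTrace(
            eye=eye,
            x=pos[:, 0] + noise[:, 0],
            y=pos[:, 1] + noise[:, 1],
            valid=valid.copy(),
            rate_hz=rate,
            unit="deg",
        )

    if config.binocular:
        left = make_trace("left", rng["noise_l"])
        right = make_trace("right", rng["noise_r"])
        traces = {"left": left, "right": right, "averaged": average_eyes(left, right)}
    else:
        traces = {"right": make_trace("right", rng["noise_r"])}

    trial = Trial(trial_id=trial_id, participant_id=participant_id, traces=traces)
    return trial, truth


def simulate_dataset(
    config: SimConfig,
    n_participants: int,
    trials_per_participant: int,
    seed: int,
) -> tuple[list, dict[tuple[str, str], GroundTruth]]:
    """A cohort of participants; per-trial seeds derive from the master seed.

    Returns (participants, truths) with truths keyed by
    (participant_id, trial_id).
    """
    from .core import Participant

    root = np.random.SeedSequence(seed)
    participants = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    trial_seeds = root.generate_state(n_participants * trials_per_participant)
    k = 0
    for pi in range(n_participants):
        pid = f"p{pi + 1:02d}"
        trials = []
        for ti in range(trials_per_participant):
            tid = f"t{ti + 1:02d}"
            trial, truth = simulate_trial(
                config, int(trial_seeds[k]) % (2**31), trial_id=tid, participant_id=pid
            )
            trials.append(trial)
            truths[(pid, tid)] = truth
            k += 1
        participants.append(Participant(participant_id=pid, trials=trials))
    return participants, truths


def write_ground_truth(truths: dict[tuple[str, str], GroundTruth], path) -> None:
    """Tab-separated sidecar of true event intervals for a simulated cohort.

    Columns: participant, trial, kind, onset_idx, offset_idx, amplitude_deg,
    direction_deg.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("participant\ttrial\tkind\tonset_idx\toffset_idx"
                 "\tamplitude_deg\tdirection_deg\n")
        for (pid, tid), truth in truths.items():
            for kind in ("fixations", "saccades", "microsaccades", "glissades", "gaps"):
                for ev in getattr(truth, kind):
                    fh.write(
                        f"{pid}\t{tid}\t{kind[:-1]}\t{ev.onset_idx}\t{ev.offset_idx}"
                        f"\t{float(ev.amplitude)!r}\t{float(ev.direction_deg)!r}\n"
                    )


def read_ground_truth(path) -> dict[tuple[str, str], GroundTruth]:
    """Inverse of :func:`write_ground_truth`."""
    truths: dict[tuple[str, str], GroundTruth] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            pid, tid, kind, on, off, amp, direc = line.rstrip("\n").split("\t")
            gt = truths.setdefault((pid, tid), GroundTruth())
            getattr(gt, kind + "s").append(
                TrueEvent(int(on), int(off), float(amp), float(direc))
            )
    return truths


@dataclass
class MatchResult:
    """Outcome of detected-vs-truth interval matching."""

    precision: Optional[float]  # None when nothing was detected
    recall: float
    matches: list[tuple[int, int]]  # (detected index, truth index)
    n_detected: int
    n_truth: int


def match_events(
    detected: Sequence[GazeEvent],
    truth: Sequence[TrueEvent],
    tol_ms: float,
    rate_hz: float,
) -> MatchResult:
    """Greedy one-to-one matching of detected events to ground truth.

    A pair is admissible when the intervals overlap by at least one sample
    and the onset discrepancy is within ``tol_ms``.  Pairs are consumed in
    order of decreasing overlap; each event matches at most once.
    """
    tol = tol_ms / 1000.0 * rate_hz
    pairs = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            ov = min(d.offset_idx, t.offset_idx) - max(d.onset_idx, t.onset_idx)
            if ov >= 1 and abs(d.onset_idx - t.onset_idx) <= tol:
                pairs.append((-ov, di, ti))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matches.append((di, ti))
    precision = len(matches) / len(detected) if detected else None
    recall = len(matches) / len(truth) if truth else 1.0
    return MatchResult(
        precision=precision,
        recall=recall,
        matches=sorted(matches),
        n_detected=len(detected),
        n_truth=len(truth),
    )
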