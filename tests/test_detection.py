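"""Threshold scan, constraint filtering, binocular merging, fixation
derivation and the end-to-end detector, each checked against independent
naive oracles."""

from __future__ import annotations

import numpy as np
import pytest

import _reference as ref
from conftest import make_trace
from microsacc.core import (
    DetectorParams,
    Fixation,
    GazeEvent,
    SaccadeFilterParams,
    ValidationError,
)
from microsacc.detection import (
    apply_constraints,
    average_eyes,
    derive_fixations,
    detect_microsaccades,
    detect_saccades,
    detect_trial,
    direction_degrees,
    merge_binocular,
    threshold_candidates,
)
from microsacc.kinematics import VelocitySeries, estimate_velocity
from microsacc.synthetic_gaze import SimConfig, simulate_trial


def _series(vx, vy, rate=500.0):
    vx = np.asarray(vx, float)
    vy = np.asarray(vy, float)
    return VelocitySeries(vx=vx, vy=vy, speed=np.hypot(vx, vy),
                          defined_mask=np.ones_like(vx, bool),
                          rate_hz=rate, window=5)


class TestThresholdCandidates:
    def test_boundary_equality_is_subthreshold(self):
        # every sample exactly on the ellipse: strict inequality keeps none
        vx = np.full(20, 3.0)
        vy = np.zeros(20)
        cands = threshold_candidates(_series(vx, vy), sigma=(1.0, 1.0),
                                     lam=3.0, min_dur_samples=1)
        assert cands == []

    def test_single_run_is_returned(self):
        vx = np.zeros(30)
        vx[10:15] = 50.0
        cands = threshold_candidates(_series(vx, np.zeros(30)), (1.0, 1.0),
                                     lam=5.0, min_dur_samples=3)
        assert cands == [(10, 15)]

    def test_short_runs_dropped(self):
        vx = np.zeros(30)
        vx[10:12] = 50.0
        assert threshold_candidates(_series(vx, np.zeros(30)), (1.0, 1.0),
                                    5.0, 3) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_lambda_against_per_sample_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vx = rng.normal(0, 4, 300)
        vy = rng.normal(0, 2, 300)
        vel = _series(vx, vy)
        prev_set = None
        for lam in (3.0, 5.0, 8.0):
            cands = threshold_candidates(vel, (1.5, 1.0), lam, 1)
            got = {i for a, b in cands for i in range(a, b)}
            # brute-force per-sample scan
            expect = {
                i for i in range(300)
                if (vx[i] / (lam * 1.5)) ** 2 + (vy[i] / (lam * 1.0)) ** 2 > 1.0
            }
            assert got == expect
            if prev_set is not None:
                assert got <= prev_set
            prev_set = got


def _drift_trace_with_pulse(n=600, rate=500.0, pulse_at=300, amp=0.4,
                            dur_samples=8, seed=0):
    """Quiet Gaussian jitter with one injected displacement pulse."""
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(0, 5e-4, n))
    y = np.cumsum(rng.normal(0, 5e-4, n))
    u = np.arange(1, dur_samples + 1) / dur_samples
    prof = u - np.sin(2 * np.pi * u) / (2 * np.pi)
    x[pulse_at:pulse_at + dur_samples] += amp * prof
    x[pulse_at + dur_samples:] += amp
    return make_trace(x, y, rate=rate)


class TestApplyConstraints:
    def _setup(self, **kw):
        trace = _drift_trace_with_pulse(**kw)
        vel = estimate_velocity(trace, 5)
        fix = Fixation(id=0, onset_idx=0, offset_idx=len(trace), rate_hz=trace.rate_hz)
        return trace, vel, fix

    def test_candidate_in_ignored_fixation_head_dropped(self):
        trace, vel, fix = self._setup(pulse_at=5)
        p = DetectorParams(ignore_fix_start_ms=20.0)  # 10 samples at 500 Hz
        out = apply_constraints([(5, 13)], trace, vel, p, "microsaccade", fix)
        assert out == []
        p0 = DetectorParams(ignore_fix_start_ms=0.0, min_dur_ms=0.0)
        out0 = apply_constraints([(5, 13)], trace, vel, p0, "microsaccade", fix)
        assert len(out0) == 1

    def test_candidate_in_ignored_tail_dropped(self):
        trace, vel, fix = self._setup(pulse_at=588, dur_samples=8)
        p = DetectorParams(ignore_fix_end_ms=20.0)
        assert apply_constraints([(588, 596)], trace, vel, p,
                                 "microsaccade", fix) == []

    def test_amplitude_bound_drops_event(self):
        trace, vel, fix = self._setup(amp=1.2)
        p = DetectorParams(max_amp_deg=1.0, ignore_fix_start_ms=0.0)
        assert apply_constraints([(300, 308)], trace, vel, p,
                                 "microsaccade", fix) == []
        p_loose = DetectorParams(max_amp_deg=2.0, ignore_fix_start_ms=0.0)
        assert len(apply_constraints([(300, 308)], trace, vel, p_loose,
                                     "microsaccade", fix)) == 1

    def test_min_isi_drops_later_event(self):
        trace, vel, fix = self._setup()
        # two candidates 10 ms apart (5 samples at 500 Hz)
        p = DetectorParams(min_isi_ms=20.0, min_dur_ms=0.0,
                           ignore_fix_start_ms=0.0, max_amp_deg=None)
        out = apply_constraints([(100, 105), (110, 115), (150, 155)],
                                trace, vel, p, "microsaccade", fix)
        assert [(e.onset_idx, e.offset_idx) for e in out] == [(100, 105), (150, 155)]

    @pytest.mark.parametrize("seed", range(10))
    def test_min_isi_matches_bruteforce_scan(self, seed):
        trace, vel, fix = self._setup()
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(10, 580, 4), size=12, replace=False))
        cands = [(int(s), int(s) + 3) for s in starts]
        p = DetectorParams(min_isi_ms=rng.choice([8.0, 16.0, 30.0]),
                           min_dur_ms=0.0, ignore_fix_start_ms=0.0,
                           max_amp_deg=None)
        out = apply_constraints(cands, trace, vel, p, "microsaccade", fix)
        # independent left-to-right keep/drop scan
        isi = ref.ms_to_samples(p.min_isi_ms, 500.0)
        expect = []
        for a, b in cands:
            if expect and a - expect[-1][1] < isi:
                continue
            expect.append((a, b))
        assert [(e.onset_idx, e.offset_idx) for e in out] == expect

    def test_gap_guard_drops_nearby_candidate(self):
        trace = _drift_trace_with_pulse()
        valid = np.ones(len(trace), bool)
        valid[320:330] = False
        trace = make_trace(trace.x, trace.y, valid=valid)
        vel = estimate_velocity(trace, 5)
        fix = Fixation(id=0, onset_idx=0, offset_idx=600, rate_hz=500.0)
        p = DetectorParams(ignore_around_missing_ms=40.0,  # 20 samples
                           ignore_fix_start_ms=0.0, min_dur_ms=0.0,
                           max_amp_deg=None)
        assert apply_constraints([(300, 308)], trace, vel, p,
                                 "microsaccade", fix) == []
        p0 = DetectorParams(ignore_around_missing_ms=0.0,
                            ignore_fix_start_ms=0.0, min_dur_ms=0.0,
                            max_amp_deg=None)
        assert len(apply_constraints([(300, 308)], trace, vel, p0,
                                     "microsaccade", fix)) == 1


def _ev(onset, offset, eye="left", rate=500.0):
    return GazeEvent(kind="microsaccade", eye=eye, onset_idx=onset,
                     offset_idx=offset, rate_hz=rate, dx=0.1, dy=0.0,
                     amp_x=0.1, amp_y=0.0, amplitude=0.1, peak_velocity=20.0,
                     direction_deg=0.0)


class TestMergeBinocular:
    def test_identical_intervals_merge_to_one(self):
        out = merge_binocular([_ev(10, 20)], [_ev(10, 20, "right")])
        assert len(out) == 1
        assert (out[0].onset_idx, out[0].offset_idx) == (10, 20)
        assert out[0].eye == "binocular"

    def test_disjoint_intervals_give_nothing(self):
        assert merge_binocular([_ev(10, 20)], [_ev(30, 40, "right")]) == []

    def test_union_interval_and_mean_kinematics(self):
        le = _ev(10, 20)
        re = _ev(15, 25, "right")
        re.amplitude = 0.3
        re.peak_velocity = 40.0
        out = merge_binocular([le], [re])
        assert (out[0].onset_idx, out[0].offset_idx) == (10, 25)
        assert out[0].amplitude == pytest.approx(0.2)
        assert out[0].peak_velocity == pytest.approx(30.0)

    def test_each_event_used_at_most_once(self):
        left = [_ev(0, 10), _ev(20, 30)]
        right = [_ev(5, 25, "right")]  # overlaps both
        out = merge_binocular(left, right)
        assert len(out) == 1
        # larger overlap with the second left event? 0..10 gives 5, 20..25
        # gives 5 -> tie broken by earlier left index
        assert out[0].onset_idx == 0

    def test_count_bounded_by_min_of_eyes(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            def rand_events(eye):
                starts = np.sort(rng.choice(np.arange(0, 200, 4), 6, replace=False))
                return [_ev(int(s), int(s) + int(rng.integers(2, 5)), eye)
                        for s in starts]
            l, r = rand_events("left"), rand_events("right")
            out = merge_binocular(l, r)
            assert len(out) <= min(len(l), len(r))

    @pytest.mark.parametrize("seed", range(15))
    def test_total_overlap_not_worse_than_exhaustive_on_detected_events(self, seed):
        # realistic near-1:1 binocular events: jittered copies of one set
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 300, 12), 5, replace=False))
        left = [_ev(int(s), int(s) + 6) for s in starts]
        right = [_ev(int(s + rng.integers(-2, 3)),
                     int(s + 6 + rng.integers(-2, 3)), "right") for s in starts]
        got = merge_binocular(left, right)
        got_iv = [(e.onset_idx, e.offset_idx) for e in got]
        # exhaustive maximum-total-overlap one-to-one matching
        import itertools
        best = -1
        best_iv = None
        li = list(range(len(left)))
        for k in range(len(right), -1, -1):
            for rsub in itertools.permutations(range(len(right)), k):
                for lsub in itertools.combinations(li, k):
                    tot = 0
                    ivs = []
                    ok = True
                    for l_i, r_i in zip(lsub, rsub):
                        le, re = left[l_i], right[r_i]
                        ov = (min(le.offset_idx, re.offset_idx)
                              - max(le.onset_idx, re.onset_idx))
                        if ov < 1:
                            ok = False
                            break
                        tot += ov
                        ivs.append((min(le.onset_idx, re.onset_idx),
                                    max(le.offset_idx, re.offset_idx)))
                    if ok and tot > best:
                        best = tot
                        best_iv = sorted(ivs)
        assert sorted(got_iv) == best_iv


class TestDeriveFixations:
    def _sacc(self, a, b):
        return _ev(a, b, eye="averaged")

    def test_two_saccades_three_fixations(self):
        trace = make_trace(np.zeros(1000))
        fx = derive_fixations(trace, [self._sacc(200, 220), self._sacc(600, 630)])
        assert [(f.onset_idx, f.offset_idx) for f in fx] == [
            (0, 200), (220, 600), (630, 1000)]

    def test_no_saccades_single_fixation(self):
        trace = make_trace(np.zeros(400))
        fx = derive_fixations(trace, [])
        assert [(f.onset_idx, f.offset_idx) for f in fx] == [(0, 400)]

    def test_centroid_is_mean_of_valid_samples(self):
        x = np.concatenate([np.full(50, 1.0), np.full(50, 3.0)])
        fx = derive_fixations(make_trace(x), [])
        assert fx[0].centroid[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_gap_handling_matches_interval_algebra(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        valid = np.ones(n, bool)
        for _ in range(3):
            a = int(rng.integers(0, n - 20))
            valid[a:a + int(rng.integers(5, 20))] = False
        trace = make_trace(np.zeros(n), valid=valid)
        saccades = [self._sacc(100, 120), self._sacc(300, 330)]
        fx = derive_fixations(trace, saccades, min_samples=5)
        # brute-force set subtraction on sample indices
        free = np.ones(n, bool)
        for s in saccades:
            free[s.onset_idx:s.offset_idx] = False
        free &= valid
        expect = [iv for iv in ref.missing_ranges([not f for f in free])
                  if iv[1] - iv[0] >= 5]
        assert [(f.onset_idx, f.offset_idx) for f in fx] == expect


class TestAverageEyes:
    def test_sample_wise_mean(self):
        l = make_trace([1.0, 1.0], [1.0, 1.0], eye="left")
        r = make_trace([3.0, 3.0], [3.0, 3.0], eye="right")
        avg = average_eyes(l, r)
        assert np.allclose(avg.x, 2.0) and np.allclose(avg.y, 2.0)
        assert avg.eye == "averaged"

    def test_invalid_if_either_eye_invalid(self):
        l = make_trace([1.0, 1.0], valid=[True, False], eye="left")
        r = make_trace([3.0, 3.0], eye="right")
        assert average_eyes(l, r).valid.tolist() == [True, False]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            average_eyes(make_trace([1.0], eye="left"),
                         make_trace([1.0, 2.0], eye="right"))


class TestEndToEnd:
    def test_injected_microsaccade_found(self):
        cfg = SimConfig(trial_s=4.0, ms_rate_per_s=1.0, dropout_rate_per_s=0.0,
                        glissade_prob=0.0)
        trial, truth = simulate_trial(cfg, seed=11)
        fx, ev = detect_trial(trial)
        assert len(truth.microsaccades) > 0
        for t in truth.microsaccades:
            assert any(
                min(e.offset_idx, t.offset_idx) - max(e.onset_idx, t.onset_idx) >= 1
                for e in ev
            )

    def test_min_duration_above_injection_suppresses_detection(self):
        cfg = SimConfig(trial_s=4.0, ms_dur_ms=(6.0, 18.0),
                        dropout_rate_per_s=0.0, glissade_prob=0.0)
        trial, truth = simulate_trial(cfg, seed=11)
        fx, ev = detect_trial(trial, DetectorParams(min_dur_ms=80.0))
        assert ev == []

    def test_monocular_injection_invisible_binocularly(self):
        # quiet shared signal; inject a pulse into the left eye only
        cfg = SimConfig(trial_s=4.0, ms_rate_per_s=0.0, dropout_rate_per_s=0.0,
                        glissade_prob=0.0)
        trial, _ = simulate_trial(cfg, seed=3)
        left = trial.traces["left"]
        x = left.x.copy()
        fix_mid = 600
        u = np.arange(1, 9) / 8
        prof = u - np.sin(2 * np.pi * u) / (2 * np.pi)
        x[fix_mid:fix_mid + 8] += 0.5 * prof
        x[fix_mid + 8:] += 0.5
        trial.traces["left"] = make_trace(x, left.y, eye="left")
        fx = derive_fixations(trial.traces["averaged"],
                              detect_saccades(trial.traces["averaged"]))
        mono = detect_microsaccades(trial, fx, DetectorParams(eye_mode="left"))
        bino = detect_microsaccades(trial, fx, DetectorParams(eye_mode="binocular"))
        mono_hit = [e for e in mono if e.onset_idx in range(fix_mid - 4, fix_mid + 8)]
        bino_hit = [e for e in bino if e.onset_idx in range(fix_mid - 4, fix_mid + 8)]
        assert len(mono_hit) == 1
        assert len(bino_hit) == 0

    def test_two_large_saccades_found(self, sim_trial):
        trial, truth = sim_trial
        sacc = detect_saccades(trial.traces["averaged"])
        assert len(sacc) == len(truth.saccades)
        for s, t in zip(sacc, truth.saccades):
            assert abs(s.onset_idx - t.onset_idx) <= 3

    def test_pure_drift_has_no_saccades(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(0, 1e-3, 2000))
        y = np.cumsum(rng.normal(0, 1e-3, 2000))
        assert detect_saccades(make_trace(x, y)) == []

    def test_events_inside_fixations_and_bounds_hold(self, sim_trial,
                                                     default_params):
        trial, _ = sim_trial
        fx, ev = detect_trial(trial, default_params)
        spans = {f.id: (f.onset_idx, f.offset_idx) for f in fx}
        for e in ev:
            a, b = spans[e.fixation_id]
            assert a <= e.onset_idx < e.offset_idx <= b
            assert e.duration_ms >= default_params.min_dur_ms
            assert e.amplitude <= default_params.max_amp_deg
            assert e.amplitude >= np.hypot(e.dx, e.dy) - 1e-9
        for e1, e2 in zip(ev, ev[1:]):
            if e1.fixation_id == e2.fixation_id:
                gap_ms = (e2.onset_idx - e1.offset_idx) / trial.rate_hz * 1000
                assert gap_ms >= default_params.min_isi_ms - 1e-9

    def test_missing_eye_mode_is_error(self):
        cfg = SimConfig(trial_s=3.0, binocular=False)
        trial, _ = simulate_trial(cfg, seed=1)
        with pytest.raises(ValidationError, match="left"):
            detect_trial(trial, DetectorParams(eye_mode="left"))

    def test_pixel_traces_rejected(self):
        trial, _ = simulate_trial(SimConfig(trial_s=3.0), seed=1)
        for tr in trial.traces.values():
            tr.unit = "px"
        with pytest.raises(ValidationError, match="degree"):
            detect_microsaccades(trial, [], DetectorParams())


class TestReferenceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("eye_mode", ["binocular", "left", "averaged"])
    def test_pipeline_matches_naive_reference(self, seed, eye_mode):
        cfg = SimConfig(trial_s=4.0)
        trial, truth = simulate_trial(cfg, seed=100 + seed)
        params = DetectorParams(eye_mode=eye_mode)
        fix = derive_fixations(trial.traces["averaged"],
                               detect_saccades(trial.traces["averaged"]))
        got = detect_microsaccades(trial, fix, params)
        got_iv = sorted((e.onset_idx, e.offset_idx) for e in got)
        expect = ref.detect_trial_reference(trial, fix, params)
        assert got_iv == expect
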