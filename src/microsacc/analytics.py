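"""Derived statistics: circular direction analysis, next-fixation rotation,
temporal and kinematic histograms, main-sequence data and multi-level
summaries.

Angle convention (shared with :mod:`microsacc.detection`): 0 deg points
rightward on screen and angles grow counter-clockwise after flipping the
downward screen-y axis, so "up on screen" is 90 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Fixation, GazeEvent, GazeTrace, Trial, ValidationError
from .detection import direction_degrees

__all__ = [
    "RoseHistogram",
    "SummaryStats",
    "inter_fixation_direction",
    "rotate_to_next_fixation",
    "rose_histogram",
    "temporal_histogram",
    "main_sequence",
    "positions_relative_to_fixation",
    "summary_statistics",
    "circular_mean_deg",
    "circular_sd_deg",
]


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean direction, ``atan2(mean sin, mean cos)`` in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def circular_sd_deg(angles_deg: np.ndarray) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` expressed in degrees.

    ``R`` is the mean resultant length; R -> 1 gives 0 and R -> 0 diverges.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    r = float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))
    r = min(r, 1.0)
    if r <= 0.0:
        return float("inf")
    return float(np.degrees(math.sqrt(-2.0 * math.log(r))))


@dataclass
class RoseHistogram:
    """Angular histogram over half-open bins partitioning [0, 360).

    ``counts`` holds the totals; ``by_condition`` the per-label counts, which
    sum to the totals.  ``mean_dir_deg``/``circ_sd_deg`` are None for empty
    input (undefined direction).
    """

    n_bins: int
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    mean_dir_deg: Optional[float]
    circ_sd_deg: Optional[float]
    by_condition: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_start_deg": self.bin_edges_deg[:-1],
                "bin_stop_deg": self.bin_edges_deg[1:],
                "count": self.counts,
            }
        )
        for label, cts in sorted(self.by_condition.items()):
            df[f"count_{label}"] = cts
        return df


def inter_fixation_direction(fix_a: Fixation, fix_b: Fixation) -> float:
    """Direction of the vector between two fixation centroids, in degrees.

    Raises
    ------
    ValidationError
        If the centroids coincide (undefined direction).
    """
    dx = fix_b.centroid[0] - fix_a.centroid[0]
    dy = fix_b.centroid[1] - fix_a.centroid[1]
    if dx == 0.0 and dy == 0.0:
        raise ValidationError(
            f"fixations {fix_a.id} and {fix_b.id} share a centroid; "
            "inter-fixation direction undefined"
        )
    return direction_degrees(dx, dy)


def rotate_to_next_fixation(
    events: Sequence[GazeEvent], fixations: Sequence[Fixation]
) -> tuple[np.ndarray, int]:
    """Event directions relative to the direction toward the next fixation.

    A relative angle of 0 deg means the event moved toward the next
    fixation's centroid.  Events owned by the last fixation of the trial have
    no successor; they are excluded and counted.

    Returns
    -------
    (relative_angles_deg, n_excluded)
    """
    fix_by_id = {f.id: f for f in fixations}
    order = sorted(fixations, key=lambda f: f.onset_idx)
    successor = {a.id: b for a, b in zip(order, order[1:])}
    rel: list[float] = []
    excluded = 0
    for ev in events:
        if ev.fixation_id is None or ev.fixation_id not in successor:
            excluded += 1
            continue
        fix = fix_by_id[ev.fixation_id]
        ref = inter_fixation_direction(fix, successor[fix.id])
        rel.append((ev.direction_deg - ref) % 360.0)
    return np.asarray(rel, dtype=float), excluded


def rose_histogram(
    angles_deg: Iterable[float],
    n_bins: int = 12,
    condition_labels: Sequence[str] | None = None,
) -> RoseHistogram:
    """Bin directions into ``n_bins`` half-open sectors of [0, 360).

    Bin ``k`` covers ``[k*360/n, (k+1)*360/n)``.  With ``condition_labels``
    (one label per angle) per-condition counts are kept alongside the totals.
    """
    if n_bins < 1:
        raise ValidationError(f"need at least 1 bin, got {n_bins}")
    angles = np.asarray(list(angles_deg), dtype=float) % 360.0
    if condition_labels is not None and len(condition_labels) != len(angles):
        raise ValidationError("condition_labels must match angles in length")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.minimum((angles // (360.0 / n_bins)).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins) if len(angles) else np.zeros(n_bins, int)
    by_cond: dict[str, np.ndarray] = {}
    if condition_labels is not None:
        for label in sorted(set(condition_labels)):
            sel = np.asarray([c == label for c in condition_labels])
            by_cond[label] = (
                np.bincount(idx[sel], minlength=n_bins) if sel.any() else np.zeros(n_bins, int)
            )
    if len(angles):
        mean_dir = circular_mean_deg(angles)
        sd = circular_sd_deg(angles)
    else:
        mean_dir = None
        sd = None
    return RoseHistogram(
        n_bins=n_bins,
        bin_edges_deg=edges,
        counts=counts,
        mean_dir_deg=mean_dir,
        circ_sd_deg=sd,
        by_condition=by_cond,
    )


def temporal_histogram(
    events: Sequence[GazeEvent],
    bin_ms: float = 40.0,
    n_bins: int | None = None,
) -> np.ndarray:
    """Histogram of event onsets measured from their fixation's onset.

    Bin ``k`` covers ``[k*bin_ms, (k+1)*bin_ms)`` milliseconds.  ``n_bins``
    fixes the output length (later onsets are dropped); otherwise the
    histogram is sized to the latest onset.
    """
    lat = [ev.t_in_fixation_ms for ev in events if ev.t_in_fixation_ms is not None]
    if not lat:
        return np.zeros(n_bins or 0, dtype=int)
    idx = (np.asarray(lat) // bin_ms).astype(int)
    if n_bins is None:
        n_bins = int(idx.max()) + 1
    counts = np.zeros(n_bins, dtype=int)
    for i in idx:
        if i < n_bins:
            counts[i] += 1
    return counts


def main_sequence(events: Sequence[GazeEvent]) -> tuple[pd.DataFrame, int]:
    """(amplitude, peak velocity) pairs for log-log main-sequence plots.

    Events with non-positive amplitude or peak velocity cannot appear on a
    logarithmic scale; they are excluded and counted.  No fit is performed.
    """
    rows = []
    excluded = 0
    for ev in events:
        if ev.amplitude > 0 and ev.peak_velocity > 0:
            rows.append((ev.amplitude, ev.peak_velocity))
        else:
            excluded += 1
    df = pd.DataFrame(rows, columns=["amplitude_deg", "peak_velocity_degs"])
    return df, excluded


def positions_relative_to_fixation(
    trace: GazeTrace,
    fixations: Sequence[Fixation],
    events: Sequence[GazeEvent] = (),
    rotate_to_next: bool = False,
) -> pd.DataFrame:
    """Fixation samples translated so each fixation centroid is the origin.

    With ``rotate_to_next`` the samples of each fixation are additionally
    rotated so the direction toward the next fixation points up on screen
    (negative y).  Samples inside a microsaccade of the owning fixation are
    flagged.  The last fixation is dropped in rotate mode (no successor).

    Returns a tidy frame with columns
    ``fixation_id, sample_idx, x, y, is_microsaccade``.
    """
    order = sorted(fixations, key=lambda f: f.onset_idx)
    successor = {a.id: b for a, b in zip(order, order[1:])}
    ms_by_fix: dict[int, list[GazeEvent]] = {}
    for ev in events:
        if ev.fixation_id is not None:
            ms_by_fix.setdefault(ev.fixation_id, []).append(ev)
    frames = []
    for fix in order:
        if rotate_to_next and fix.id not in successor:
            continue
        sl = slice(fix.onset_idx, fix.offset_idx)
        x = trace.x[sl] - fix.centroid[0]
        y = trace.y[sl] - fix.centroid[1]
        if rotate_to_next:
            ref = inter_fixation_direction(fix, successor[fix.id])
            # rotate so that direction `ref` maps to "up on screen" (90 deg);
            # work in the flipped-y frame where angles are standard
            phi = np.radians(90.0 - ref)
            yu = -y
            xr = x * np.cos(phi) - yu * np.sin(phi)
            yu_r = x * np.sin(phi) + yu * np.cos(phi)
            x, y = xr, -yu_r
        idx = np.arange(fix.onset_idx, fix.offset_idx)
        flag = np.zeros(len(idx), dtype=bool)
        for ev in ms_by_fix.get(fix.id, []):
            flag[(idx >= ev.onset_idx) & (idx < ev.offset_idx)] = True
        frames.append(
            pd.DataFrame(
                {
                    "fixation_id": fix.id,
                    "sample_idx": idx,
                    "x": x,
                    "y": y,
                    "is_microsaccade": flag,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["fixation_id", "sample_idx", "x", "y", "is_microsaccade"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SummaryStats:
    """Aggregated descriptives at fixation, trial, participant or condition
    level.

    Rates: ``ms_per_second`` normalises by total *fixation* time (detection
    is fixation-scoped), ``ms_per_fixation`` by fixation count.
    ``isi_*`` describe gaps between consecutive microsaccade onsets within a
    fixation, in ms.  Mean/SD fields are NaN when no events contribute.
    """

    level: str
    participant_id: Optional[str] = None
    condition: Optional[str] = None
    trial_id: Optional[str] = None
    fixation_count: int = 0
    fixation_duration_mean_ms: float = float("nan")
    fixation_duration_sd_ms: float = float("nan")
    total_fixation_time_s: float = 0.0
    pct_fixations_with_ms: float = float("nan")
    ms_count: int = 0
    ms_duration_mean_ms: float = float("nan")
    ms_duration_sd_ms: float = float("nan")
    ms_amplitude_mean_deg: float = float("nan")
    ms_amplitude_sd_deg: float = float("nan")
    ms_peak_velocity_mean_degs: float = float("nan")
    ms_peak_velocity_sd_degs: float = float("nan")
    ms_per_second: float = float("nan")
    ms_per_fixation: float = float("nan")
    isi_mean_ms: float = float("nan")
    isi_sd_ms: float = float("nan")


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    if len(values) == 0:
        return float("nan"), float("nan")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def _isis_ms(events: Sequence[GazeEvent]) -> list[float]:
    """Onset-to-onset gaps between consecutive microsaccades sharing a
    fixation."""
    # callers pass one trial's events at a time, so fixation_id is a
    # sufficient grouping key
    groups: dict[int, list[GazeEvent]] = {}
    for ev in events:
        if ev.fixation_id is not None:
            groups.setdefault(ev.fixation_id, []).append(ev)
    isis = []
    for evs in groups.values():
        evs = sorted(evs, key=lambda e: e.onset_idx)
        for a, b in zip(evs, evs[1:]):
            isis.append((b.onset_idx - a.onset_idx) / a.rate_hz * 1000.0)
    return isis


def _summarise(
    level: str,
    fixations: Sequence[Fixation],
    events: Sequence[GazeEvent],
    isis: Sequence[float],
    **ids,
) -> SummaryStats:
    s = SummaryStats(level=level, **ids)
    s.fixation_count = len(fixations)
    s.total_fixation_time_s = sum(f.duration_ms for f in fixations) / 1000.0
    s.fixation_duration_mean_ms, s.fixation_duration_sd_ms = _mean_sd(
        [f.duration_ms for f in fixations]
    )
    s.ms_count = len(events)
    s.ms_duration_mean_ms, s.ms_duration_sd_ms = _mean_sd(
        [e.duration_ms for e in events]
    )
    s.ms_amplitude_mean_deg, s.ms_amplitude_sd_deg = _mean_sd(
        [e.amplitude for e in events]
    )
    s.ms_peak_velocity_mean_degs, s.ms_peak_velocity_sd_degs = _mean_sd(
        [e.peak_velocity for e in events]
    )
    if s.fixation_count:
        with_ms = sum(1 for f in fixations if f.microsaccade_ids)
        s.pct_fixations_with_ms = 100.0 * with_ms / s.fixation_count
        s.ms_per_fixation = s.ms_count / s.fixation_count
    if s.total_fixation_time_s > 0:
        s.ms_per_second = s.ms_count / s.total_fixation_time_s
    s.isi_mean_ms, s.isi_sd_ms = _mean_sd(list(isis))
    return s


def summary_statistics(
    trials: Sequence[tuple[Trial, Sequence[Fixation], Sequence[GazeEvent]]],
    level: str = "trial",
) -> list[SummaryStats]:
    """Descriptive statistics per trial, participant, condition or overall.

    Parameters
    ----------
    trials
        Triples of (trial, fixations, detected microsaccades), i.e. detection
        has already been run.
    level
        "trial", "participant", "condition", "participant_condition" or
        "overall".  Aggregation above trial level pools raw events and
        fixations (not means of means), so a condition-level value equals
        the value computed from the pooled per-trial raw event lists.
    """
    levels = ("trial", "participant", "condition", "participant_condition", "overall")
    if level not in levels:
        raise ValidationError(f"unknown aggregation level {level!r}")

    def key(trial: Trial):
        if level == "trial":
            return (trial.participant_id, trial.trial_id, trial.condition)
        if level == "participant":
            return (trial.participant_id,)
        if level == "condition":
            return (trial.condition,)
        if level == "participant_condition":
            return (trial.participant_id, trial.condition)
        return ("all",)

    groups: dict[tuple, list[tuple[Trial, Sequence[Fixation], Sequence[GazeEvent]]]] = {}
    for item in trials:
        groups.setdefault(key(item[0]), []).append(item)

    out: list[SummaryStats] = []
    for k in sorted(groups, key=lambda t: tuple(str(x) for x in t)):
        fixations: list[Fixation] = []
        events: list[GazeEvent] = []
        isis: list[float] = []
        for trial, fx, ev in groups[k]:
            fixations.extend(fx)
            events.extend(ev)
            isis.extend(_isis_ms(list(ev)))
        ids: dict[str, Optional[str]] = {}
        if level == "trial":
            ids = {"participant_id": k[0], "trial_id": k[1], "condition": k[2]}
        elif level == "participant":
            ids = {"participant_id": k[0]}
        elif level == "condition":
            ids = {"condition": k[0]}
        elif level == "participant_condition":
            ids = {"participant_id": k[0], "condition": k[1]}
        out.append(_summarise(level, fixations, events, isis, **ids))
    return out


def stats_frame(stats: Sequence[SummaryStats]) -> pd.DataFrame:
    """Tabular view of summary statistics (one row per group)."""
    return pd.DataFrame([vars(s) for s in stats])
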