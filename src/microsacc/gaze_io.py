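"""Plain-text trial/condition formats and CSV export of aggregated statistics.

Trial file dialect (tab-separated, self-describing)
---------------------------------------------------
A header block followed by per-trial blocks with typed rows::

    FORMAT  gaze-trials     1
    PARTICIPANT     p01
    RATE    500
    UNIT    deg
    GEOMETRY        650     1920    1080    531     298.9      (optional)
    TRIAL   t01
    EYES    left    right
    S       <t>     <x>     <y>     <valid> [<x> <y> <valid> ...]
    F       <id>    <onset_idx>     <offset_idx>    <cx>    <cy>
    M       <eye>   <onset_idx>     <offset_idx>    [kinematic columns]
    E       <t>     <label>
    ENDTRIAL

* One S row per sample; timestamps in seconds at nanosecond precision.
  Internally time is sample index / rate, so round-trips are exact.
* Invalid samples carry valid = 0 and ``nan`` coordinates.
* Event intervals are half-open ``[onset_idx, offset_idx)`` sample indices —
  integers, hence bit-exact on round-trip.
* The unit tag travels with the data; no px/deg conversion happens in I/O.

The condition file is a two-column TSV ``trial_id<TAB>label``; lines starting
with ``#`` are comments.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .analytics import SummaryStats
from .core import (
    ConditionTable,
    Fixation,
    GazeEvent,
    GazeTrace,
    Participant,
    Trial,
    ValidationError,
    ViewingGeometry,
)

__all__ = [
    "ParseError",
    "read_trial_file",
    "write_trial_file",
    "write_events_file",
    "read_condition_file",
    "write_condition_file",
    "export_aggregate_csv",
    "FORMAT_NAME",
    "FORMAT_VERSION",
]

FORMAT_NAME = "gaze-trials"
FORMAT_VERSION = "1"

_EVENT_FLOAT_COLS = (
    "dx", "dy", "amp_x", "amp_y", "amplitude", "peak_velocity", "direction_deg"
)


class ParseError(ValidationError):
    """Malformed trial or condition file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------- reading


def read_trial_file(path, geometry: Optional[ViewingGeometry] = None) -> Participant:
    """Read one participant's trials from the tab-separated trial format.

    ``geometry`` overrides/supplies the viewing geometry when the file lacks
    a GEOMETRY row.  Missing-data ranges are inferred from invalid samples.
    """
    participant_id: Optional[str] = None
    rate: Optional[float] = None
    unit: Optional[str] = None
    file_geometry: Optional[ViewingGeometry] = None
    trials: list[Trial] = []

    state: Optional[dict] = None  # current trial block

    def finish_trial(lineno: int) -> None:
        nonlocal state
        if state is None:
            return
        if not state["samples"]:
            raise ParseError(path, lineno, f"trial {state['id']!r} has no samples")
        ts = np.asarray([s[0] for s in state["samples"]])
        if np.any(np.diff(ts) <= 0):
            bad = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise ParseError(
                path, lineno,
                f"trial {state['id']!r}: non-monotonic timestamp at sample {bad}",
            )
        dt = 1.0 / rate
        if len(ts) > 1 and np.any(np.abs(np.diff(ts) - dt) > 0.5 * dt):
            raise ParseError(
                path, lineno,
                f"trial {state['id']!r}: sample spacing inconsistent with "
                f"declared rate {rate} Hz",
            )
        traces: dict[str, GazeTrace] = {}
        for ei, eye in enumerate(state["eyes"]):
            x = np.asarray([s[1][ei][0] for s in state["samples"]])
            y = np.asarray([s[1][ei][1] for s in state["samples"]])
            valid = np.asarray([s[1][ei][2] for s in state["samples"]], dtype=bool)
            traces[eye] = GazeTrace(
                eye=eye, x=x, y=y, valid=valid, rate_hz=rate, unit=unit
            )
        trials.append(
            Trial(
                trial_id=state["id"],
                participant_id=participant_id,
                traces=traces,
                fixations=state["fixations"] or None,
                microsaccades=state["microsaccades"] or None,
                event_markers=state["markers"],
            )
        )
        state = None

    lineno = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t")
            tag = tok[0]
            try:
                if tag == "FORMAT":
                    if tok[1] != FORMAT_NAME:
                        raise ParseError(path, lineno, f"unknown format {tok[1]!r}")
                elif tag == "PARTICIPANT":
                    participant_id = tok[1]
                elif tag == "RATE":
                    rate = float(tok[1])
                elif tag == "UNIT":
                    if tok[1] not in ("px", "deg"):
                        raise ParseError(path, lineno, f"unknown unit {tok[1]!r}")
                    unit = tok[1]
                elif tag == "GEOMETRY":
                    file_geometry = ViewingGeometry(
                        distance_mm=float(tok[1]),
                        screen_px=(float(tok[2]), float(tok[3])),
                        screen_mm=(float(tok[4]), float(tok[5])),
                    )
                elif tag == "TRIAL":
                    finish_trial(lineno)
                    if rate is None or unit is None or participant_id is None:
                        raise ParseError(
                            path, lineno,
                            "TRIAL before complete header "
                            "(PARTICIPANT, RATE and UNIT required)",
                        )
                    state = {
                        "id": tok[1],
                        "eyes": ["averaged"],
                        "samples": [],
                        "fixations": [],
                        "microsaccades": [],
                        "markers": [],
                    }
                elif tag == "EYES":
                    state["eyes"] = tok[1:]
                elif tag == "S":
                    t = float(tok[1])
                    vals = tok[2:]
                    eyes = state["eyes"]
                    if len(vals) != 3 * len(eyes):
                        raise ParseError(
                            path, lineno,
                            f"expected {3 * len(eyes)} sample columns for "
                            f"{len(eyes)} eye(s), got {len(vals)}",
                        )
                    per_eye = []
                    for ei in range(len(eyes)):
                        x, y, v = vals[3 * ei : 3 * ei + 3]
                        per_eye.append((float(x), float(y), int(v) != 0))
                    state["samples"].append((t, per_eye))
                elif tag == "F":
                    cx = float(tok[4]) if len(tok) > 4 else math.nan
                    cy = float(tok[5]) if len(tok) > 5 else math.nan
                    state["fixations"].append(
                        Fixation(
                            id=int(tok[1]),
                            onset_idx=int(tok[2]),
                            offset_idx=int(tok[3]),
                            rate_hz=rate,
                            centroid=(cx, cy),
                        )
                    )
                elif tag == "M":
                    kin = {
                        c: (float(tok[4 + j]) if len(tok) > 4 + j else math.nan)
                        for j, c in enumerate(_EVENT_FLOAT_COLS)
                    }
                    fix_id = None
                    if len(tok) > 4 + len(_EVENT_FLOAT_COLS):
                        fld = tok[4 + len(_EVENT_FLOAT_COLS)]
                        fix_id = int(fld) if fld != "" else None
                    state["microsaccades"].append(
                        GazeEvent(
                            kind="microsaccade",
                            eye=tok[1],
                            onset_idx=int(tok[2]),
                            offset_idx=int(tok[3]),
                            rate_hz=rate,
                            fixation_id=fix_id,
                            **kin,
                        )
                    )
                elif tag == "E":
                    state["markers"].append((float(tok[1]), tok[2]))
                elif tag == "ENDTRIAL":
                    finish_trial(lineno)
                else:
                    raise ParseError(path, lineno, f"unknown row tag {tag!r}")
            except ParseError:
                raise
            except (IndexError, TypeError, ValueError) as exc:
                raise ParseError(path, lineno, f"malformed {tag} row: {exc}") from exc
        finish_trial(lineno)

    if participant_id is None:
        raise ParseError(path, 0, "file lacks a PARTICIPANT header row")
    return Participant(
        participant_id=participant_id,
        trials=trials,
        geometry=geometry or file_geometry,
    )


# ---------------------------------------------------------------- writing


def _check_disjoint(events: Sequence, what: str) -> None:
    evs = sorted(events, key=lambda e: e.onset_idx)
    for a, b in zip(evs, evs[1:]):
        if b.onset_idx < a.offset_idx:
            raise ValidationError(
                f"overlapping {what} [{a.onset_idx},{a.offset_idx}) and "
                f"[{b.onset_idx},{b.offset_idx}); refusing to write"
            )


def write_trial_file(participant: Participant, path) -> None:
    """Write a participant's trials (samples, fixations, microsaccades,
    markers) so that ``read_trial_file`` reproduces them exactly."""
    if not participant.trials:
        raise ValidationError("participant has no trials to write")
    first = participant.trials[0]
    rate = first.rate_hz
    unit = next(iter(first.traces.values())).unit
    with open(path, "w", encoding="utf-8") as fh:
        w = fh.write
        w(f"FORMAT\t{FORMAT_NAME}\t{FORMAT_VERSION}\n")
        w(f"PARTICIPANT\t{participant.participant_id}\n")
        w(f"RATE\t{_fmt(rate)}\n")
        w(f"UNIT\t{unit}\n")
        if participant.geometry is not None:
            g = participant.geometry
            w(
                "GEOMETRY\t"
                + "\t".join(
                    _fmt(v)
                    for v in (g.distance_mm, *g.screen_px, *g.screen_mm)
                )
                + "\n"
            )
        for trial in participant.trials:
            if trial.rate_hz != rate:
                raise ValidationError("all trials in one file must share a rate")
            _write_trial_block(w, trial)


def _write_trial_block(w, trial: Trial) -> None:
    eyes = sorted(trial.traces)
    w(f"TRIAL\t{trial.trial_id}\n")
    w("EYES\t" + "\t".join(eyes) + "\n")
    n = trial.n_samples
    rate = trial.rate_hz
    traces = [trial.traces[e] for e in eyes]
    for i in range(n):
        cols = [f"S\t{i / rate:.9f}"]
        for tr in traces:
            cols.append(
                f"{_fmt(tr.x[i])}\t{_fmt(tr.y[i])}\t{1 if tr.valid[i] else 0}"
            )
        w("\t".join(cols) + "\n")
    if trial.fixations:
        _check_disjoint(trial.fixations, "fixations")
        for f in sorted(trial.fixations, key=lambda f: f.onset_idx):
            w(
                f"F\t{f.id}\t{f.onset_idx}\t{f.offset_idx}\t"
                f"{_fmt(f.centroid[0])}\t{_fmt(f.centroid[1])}\n"
            )
    if trial.microsaccades:
        _check_disjoint(trial.microsaccades, "microsaccades")
        for e in sorted(trial.microsaccades, key=lambda e: e.onset_idx):
            kin = "\t".join(_fmt(getattr(e, c)) for c in _EVENT_FLOAT_COLS)
            fid = "" if e.fixation_id is None else str(e.fixation_id)
            w(f"M\t{e.eye}\t{e.onset_idx}\t{e.offset_idx}\t{kin}\t{fid}\n")
    for t, label in trial.event_markers:
        w(f"E\t{t:.9f}\t{label}\n")
    w("ENDTRIAL\n")


def write_events_file(
    trial: Trial,
    detected_fixations: Sequence[Fixation],
    detected_microsaccades: Sequence[GazeEvent],
    path,
) -> None:
    """Export one trial's raw data plus detected events for re-import.

    Events must be sorted by onset; overlapping events of the same class are
    refused.
    """
    for name, evs in (
        ("fixations", detected_fixations),
        ("microsaccades", detected_microsaccades),
    ):
        if any(
            b.onset_idx < a.onset_idx for a, b in zip(evs, list(evs)[1:])
        ):
            raise ValidationError(f"{name} must be sorted by onset")
    out = Trial(
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        traces=trial.traces,
        condition=trial.condition,
        fixations=list(detected_fixations) or None,
        microsaccades=list(detected_microsaccades) or None,
        event_markers=trial.event_markers,
    )
    write_trial_file(
        Participant(participant_id=trial.participant_id, trials=[out]), path
    )


# ------------------------------------------------------------- conditions


def read_condition_file(path) -> ConditionTable:
    """Two-column TSV mapping trial id -> condition label."""
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t")
            if len(tok) != 2:
                raise ParseError(
                    path, lineno, f"expected 2 tab-separated columns, got {len(tok)}"
                )
            tid, label = tok
            if tid in mapping:
                raise ParseError(path, lineno, f"duplicate trial id {tid!r}")
            if not label:
                raise ParseError(path, lineno, f"empty condition label for {tid!r}")
            mapping[tid] = label
    return ConditionTable(mapping)


def write_condition_file(table: ConditionTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# conditions\t{FORMAT_VERSION}\n")
        for tid, label in table.items():
            fh.write(f"{tid}\t{label}\n")


# ---------------------------------------------------------------- exports


def export_aggregate_csv(stats: Iterable[SummaryStats], path) -> None:
    """Write aggregated statistics, one row per group (e.g. participant x
    condition), as locale-independent CSV; undefined means are left empty."""
    df = pd.DataFrame([vars(s) for s in stats])
    df.to_csv(path, index=False, na_rep="")
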