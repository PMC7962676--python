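"""Shared data containers for gaze traces, detection parameters and events.

Conventions used throughout the package
---------------------------------------
* Screen coordinates: origin top-left, x to the right, y **downward**.
* Directions: 0 deg = rightward on screen, counter-clockwise positive after
  flipping screen-y, so "up on screen" = 90 deg; angles live in [0, 360).
* Sample indices are 0-based; every event interval is half-open
  ``[onset_idx, offset_idx)`` in sample indices.
* Time is represented internally as sample index / sampling rate, which keeps
  round-trips through text files exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ViewingGeometry",
    "GazeTrace",
    "Trial",
    "Participant",
    "ConditionTable",
    "DetectorParams",
    "SaccadeFilterParams",
    "GazeEvent",
    "Fixation",
    "ParameterError",
    "ValidationError",
    "DegenerateSignalError",
    "MIN_RATE_HZ",
]

MIN_RATE_HZ = 200.0


class ParameterError(ValueError):
    """Invalid detector or filter parameter value."""


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class DegenerateSignalError(ValueError):
    """Velocity dispersion is (numerically) zero: constant or duplicated data."""


@dataclass(frozen=True)
class ViewingGeometry:
    """Screen and observer geometry needed for the pixel-to-degree mapping.

    Parameters
    ----------
    distance_mm
        Eye-to-screen viewing distance in millimetres.
    screen_px
        Screen resolution ``(width, height)`` in pixels.
    screen_mm
        Physical screen size ``(width, height)`` in millimetres.
    """

    distance_mm: float
    screen_px: tuple[float, float]
    screen_mm: tuple[float, float]

    def __post_init__(self) -> None:
        vals = (self.distance_mm, *self.screen_px, *self.screen_mm)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValidationError("viewing geometry values must all be positive")

    @property
    def mm_per_px(self) -> tuple[float, float]:
        return (
            self.screen_mm[0] / self.screen_px[0],
            self.screen_mm[1] / self.screen_px[1],
        )


@dataclass
class GazeTrace:
    """One eye's uniformly sampled position time series.

    ``x``/``y`` of invalid samples carry NaN; their original values are not
    meaningful.  ``missing_ranges`` (half-open sample-index intervals) are
    derived from the validity mask: consecutive invalid samples coalesce.
    """

    eye: str  # {"left", "right", "averaged"}
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float
    unit: str  # {"px", "deg"}

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.x.shape == self.y.shape == self.valid.shape):
            raise ValidationError("x, y and valid must have equal length")
        if self.eye not in ("left", "right", "averaged"):
            raise ValidationError(f"unknown eye label {self.eye!r}")
        if self.unit not in ("px", "deg"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.rate_hz < MIN_RATE_HZ:
            warnings.warn(
                f"sampling rate {self.rate_hz} Hz is below the {MIN_RATE_HZ:.0f} Hz "
                "minimum recommended for microsaccade detection",
                stacklevel=2,
            )
        # hide positions of invalid samples
        self.x = np.where(self.valid, self.x, np.nan)
        self.y = np.where(self.valid, self.y, np.nan)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def t(self) -> np.ndarray:
        """Timestamps in seconds (sample index / rate)."""
        return np.arange(len(self.x)) / self.rate_hz

    @property
    def missing_ranges(self) -> list[tuple[int, int]]:
        """Half-open ``[start, stop)`` sample-index runs of invalid samples."""
        return mask_to_intervals(~self.valid)

    def copy_with(self, **kw) -> "GazeTrace":
        return replace(self, **kw)


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class GazeEvent:
    """A detected microsaccade or saccade.

    Kinematics:

    * ``dx, dy`` — start-to-end displacement in degrees (screen coordinates).
    * ``amp_x, amp_y`` — sign-carrying coordinate ranges over the event;
      ``amplitude = hypot(amp_x, amp_y)`` (never smaller than the
      displacement norm).
    * ``peak_velocity`` — maximum sample speed within the event, deg/s.
    * ``direction_deg`` — direction of the start-to-end vector in [0, 360),
      0 = rightward, 90 = up on screen.
    """

    kind: str  # {"microsaccade", "saccade"}
    eye: str
    onset_idx: int
    offset_idx: int
    rate_hz: float
    dx: float
    dy: float
    amp_x: float
    amp_y: float
    amplitude: float
    peak_velocity: float
    direction_deg: float
    fixation_id: Optional[int] = None
    t_in_fixation_ms: Optional[float] = None
    partner: Optional["GazeEvent"] = None

    @property
    def onset_t(self) -> float:
        return self.onset_idx / self.rate_hz

    @property
    def offset_t(self) -> float:
        return self.offset_idx / self.rate_hz

    @property
    def duration_ms(self) -> float:
        return (self.offset_idx - self.onset_idx) / self.rate_hz * 1000.0

    @property
    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx


@dataclass
class Fixation:
    """An inter-saccade interval owning zero or more microsaccades."""

    id: int
    onset_idx: int
    offset_idx: int
    rate_hz: float
    centroid: tuple[float, float] = (np.nan, np.nan)
    microsaccade_ids: list[int] = field(default_factory=list)

    @property
    def onset_t(self) -> float:
        return self.onset_idx / self.rate_hz

    @property
    def offset_t(self) -> float:
        return self.offset_idx / self.rate_hz

    @property
    def duration_ms(self) -> float:
        return (self.offset_idx - self.onset_idx) / self.rate_hz * 1000.0

    @property
    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx


@dataclass
class Trial:
    """All per-trial data: traces per eye plus optional precomputed events."""

    trial_id: str
    participant_id: str
    traces: dict[str, GazeTrace]
    condition: Optional[str] = None
    fixations: Optional[list[Fixation]] = None
    microsaccades: Optional[list[GazeEvent]] = None
    event_markers: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValidationError(f"trial {self.trial_id!r} has no gaze traces")
        lengths = {len(tr) for tr in self.traces.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"trial {self.trial_id!r}: traces differ in length {sorted(lengths)}"
            )
        n = lengths.pop()
        for evs in (self.fixations or []), (self.microsaccades or []):
            for ev in evs:
                if not (0 <= ev.onset_idx < ev.offset_idx <= n):
                    raise ValidationError(
                        f"trial {self.trial_id!r}: event [{ev.onset_idx}, "
                        f"{ev.offset_idx}) outside trace span [0, {n})"
                    )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values())))

    @property
    def rate_hz(self) -> float:
        return next(iter(self.traces.values())).rate_hz

    def trace(self, eye: str) -> GazeTrace:
        try:
            return self.traces[eye]
        except KeyError:
            raise ValidationError(
                f"trial {self.trial_id!r} has no {eye!r} eye data "
                f"(available: {sorted(self.traces)})"
            ) from None


@dataclass
class Participant:
    """One participant's trials as read from a trial file."""

    participant_id: str
    trials: list[Trial]
    geometry: Optional[ViewingGeometry] = None


class ConditionTable:
    """Mapping trial id -> condition label, joined onto trials explicitly."""

    def __init__(self, mapping: dict[str, str]):
        for tid, label in mapping.items():
            if not label:
                raise ValidationError(f"empty condition label for trial {tid!r}")
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __getitem__(self, trial_id: str) -> str:
        return self._map[trial_id]

    def __contains__(self, trial_id: str) -> bool:
        return trial_id in self._map

    def items(self):
        return self._map.items()

    def apply(self, trials: list[Trial]) -> None:
        """Attach labels; every table entry must match a known trial id."""
        known = {t.trial_id for t in trials}
        unknown = set(self._map) - known
        if unknown:
            raise ValidationError(
                f"condition table references unknown trial ids: {sorted(unknown)}"
            )
        for t in trials:
            if t.trial_id in self._map:
                t.condition = self._map[t.trial_id]


def _positive(name: str, value: float) -> None:
    if value is not None and value < 0:
        raise ParameterError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class DetectorParams:
    """Microsaccade-filter parameters.

    Defaults follow the common literature settings for fixational-eye-movement
    work: lambda = 5, minimum duration 6 ms, velocity window 5 samples,
    binocular detection, maximum amplitude 1 deg, minimum inter-saccadic
    interval 20 ms, and the first 20 ms of each fixation ignored (glissade
    guard).

    Parameters
    ----------
    lam
        Unitless multiplier on the robust velocity dispersion; the elliptic
        threshold is ``(vx/(lam*sx))**2 + (vy/(lam*sy))**2 > 1``.
    min_dur_ms, max_dur_ms
        Event duration bounds in milliseconds (``None`` disables a bound).
    min_amp_deg, max_amp_deg
        Amplitude bounds in visual degrees.
    min_pv_degs, max_pv_degs
        Peak-velocity bounds in deg/s.
    vel_window
        Moving-average velocity window, odd sample count >= 3.
    ignore_fix_start_ms, ignore_fix_end_ms
        Time ignored at the beginning / end of each fixation (glissade guard).
    min_isi_ms
        Minimum inter-saccadic interval; a later event starting sooner than
        this after the previous kept event is discarded (overshoot guard).
    ignore_around_missing_ms
        Guard band around missing-data gaps.
    eye_mode
        {"left", "right", "averaged", "binocular"}.
    sigma_scope
        {"trial", "fixation"} — pool the dispersion estimate over all
        fixation samples of the trial, or estimate it per fixation.
    """

    lam: float = 5.0
    min_dur_ms: float = 6.0
    max_dur_ms: Optional[float] = None
    min_amp_deg: Optional[float] = None
    max_amp_deg: Optional[float] = 1.0
    min_pv_degs: Optional[float] = None
    max_pv_degs: Optional[float] = None
    vel_window: int = 5
    ignore_fix_start_ms: float = 20.0
    ignore_fix_end_ms: float = 0.0
    min_isi_ms: float = 20.0
    ignore_around_missing_ms: float = 0.0
    eye_mode: str = "binocular"
    sigma_scope: str = "trial"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ParameterError(f"lambda must be positive, got {self.lam}")
        if self.vel_window < 3 or self.vel_window % 2 == 0:
            raise ParameterError(
                f"velocity window must be an odd integer >= 3, got {self.vel_window}"
            )
        for name in (
            "min_dur_ms",
            "max_dur_ms",
            "min_amp_deg",
            "max_amp_deg",
            "min_pv_degs",
            "max_pv_degs",
            "ignore_fix_start_ms",
            "ignore_fix_end_ms",
            "min_isi_ms",
            "ignore_around_missing_ms",
        ):
            _positive(name, getattr(self, name))
        for lo, hi in (
            (self.min_dur_ms, self.max_dur_ms),
            (self.min_amp_deg, self.max_amp_deg),
            (self.min_pv_degs, self.max_pv_degs),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ParameterError(f"bound minimum {lo} exceeds maximum {hi}")
        if self.eye_mode not in ("left", "right", "averaged", "binocular"):
            raise ParameterError(f"unknown eye mode {self.eye_mode!r}")
        if self.sigma_scope not in ("trial", "fixation"):
            raise ParameterError(f"unknown sigma scope {self.sigma_scope!r}")


@dataclass(frozen=True)
class SaccadeFilterParams:
    """Saccade-filter parameters: the same algorithm run on the whole trial.

    Defaults: lambda = 8, minimum duration 3 ms, velocity window 9 samples,
    minimum amplitude 1 deg (suppresses fixational events), minimum
    inter-saccadic interval 50 ms.
    """

    lam: float = 8.0
    min_dur_ms: float = 3.0
    max_dur_ms: Optional[float] = None
    min_amp_deg: Optional[float] = 1.0
    max_amp_deg: Optional[float] = None
    min_pv_degs: Optional[float] = None
    max_pv_degs: Optional[float] = None
    vel_window: int = 9
    min_isi_ms: float = 50.0
    ignore_around_missing_ms: float = 0.0

    def __post_init__(self) -> None:
        DetectorParams.__post_init__(self)  # type: ignore[arg-type]

    # fields DetectorParams validation touches but saccade filtering lacks
    ignore_fix_start_ms: float = 0.0
    ignore_fix_end_ms: float = 0.0
    eye_mode: str = "averaged"
    sigma_scope: str = "trial"
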