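"""Unit conversion and velocity estimation.

The velocity estimator is the moving-average central-difference stencil used
in velocity-threshold event detection for fixational eye movements.  For a
window of ``2m + 1`` samples,

    v[n] = sum_{k=1..m} (x[n+k] - x[n-k]) / (2 * dt * sum_{k=1..m} k)

which for the common 5-sample window reduces to

    v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (6 * dt).

The stencil is exact on affine signals for every window size.  Velocity is
left undefined (masked) wherever the stencil would touch a trace edge or an
invalid sample; no interpolation across gaps is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateSignalError,
    GazeTrace,
    ParameterError,
    ValidationError,
    ViewingGeometry,
)

__all__ = [
    "VelocitySeries",
    "pixels_to_degrees",
    "estimate_velocity",
    "robust_sigma",
    "SIGMA_FLOOR_DEGS",
    "MIN_SIGMA_SAMPLES",
]

#: Dispersion below this value (deg/s) is treated as a degenerate signal.
SIGMA_FLOOR_DEGS = 1e-10

#: Minimum number of defined velocity samples required to estimate sigma.
MIN_SIGMA_SAMPLES = 10


@dataclass
class VelocitySeries:
    """Per-sample horizontal/vertical velocity and speed, with a defined mask.

    ``speed = hypot(vx, vy)`` wherever ``defined_mask`` is true; undefined
    samples carry NaN.
    """

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    defined_mask: np.ndarray
    rate_hz: float
    window: int

    def __len__(self) -> int:
        return len(self.vx)


def pixels_to_degrees(trace: GazeTrace, geometry: ViewingGeometry) -> GazeTrace:
    """Map pixel coordinates to visual angles about the screen centre.

    Each axis is converted independently:
    ``theta = atan((p - c) * mm_per_px / distance_mm)`` in degrees, where
    ``c`` is the screen-centre coordinate on that axis.  The screen-down
    y direction keeps its sign (y in degrees still increases downward).
    """
    if geometry is None:
        raise ValidationError(
            "pixel data requires viewing geometry (distance and screen size) "
            "for conversion to visual degrees"
        )
    if trace.unit != "px":
        raise ValidationError(f"trace unit is {trace.unit!r}, expected 'px'")
    mmx, mmy = geometry.mm_per_px
    cx = geometry.screen_px[0] / 2.0
    cy = geometry.screen_px[1] / 2.0
    x_deg = np.degrees(np.arctan((trace.x - cx) * mmx / geometry.distance_mm))
    y_deg = np.degrees(np.arctan((trace.y - cy) * mmy / geometry.distance_mm))
    return trace.copy_with(x=x_deg, y=y_deg, unit="deg")


def _stencil_weights(window: int) -> tuple[int, float]:
    m = (window - 1) // 2
    norm = 2.0 * sum(range(1, m + 1))  # 2 * sum k
    return m, norm


def estimate_velocity(trace: GazeTrace, window_samples: int) -> VelocitySeries:
    """Moving-average velocity of a trace.

    Parameters
    ----------
    trace
        Gaze trace in visual degrees.
    window_samples
        Odd stencil width >= 3 and <= trace length.

    Returns
    -------
    VelocitySeries
        deg/s per sample; masked within ``(window-1)/2`` samples of the trace
        ends and wherever the stencil covers an invalid sample.
    """
    n = len(trace)
    w = int(window_samples)
    if w < 3 or w % 2 == 0:
        raise ParameterError(f"velocity window must be odd and >= 3, got {window_samples}")
    if w > n:
        raise ParameterError(f"velocity window {w} exceeds trace length {n}")
    m, norm = _stencil_weights(w)
    dt = trace.dt

    x = trace.x
    y = trace.y
    vx = np.zeros(n)
    vy = np.zeros(n)
    # defined iff all samples n-m..n+m valid and inside the trace
    ok = trace.valid.astype(float)
    defined = np.ones(n, dtype=bool)
    for k in range(-m, m + 1):
        shifted = np.zeros(n)
        shifted[max(0, -k) : n - max(0, k)] = ok[max(0, k) : n + min(0, k)]
        defined &= shifted > 0.5
    for k in range(1, m + 1):
        fwd = np.full(n, np.nan)
        bwd = np.full(n, np.nan)
        fwd[:-k] = x[k:]
        bwd[k:] = x[:-k]
        vx += np.where(defined, fwd - bwd, 0.0)
        fwd[:-k] = y[k:]
        bwd[k:] = y[:-k]
        vy += np.where(defined, fwd - bwd, 0.0)
    vx = np.where(defined, vx / (norm * dt), np.nan)
    vy = np.where(defined, vy / (norm * dt), np.nan)
    speed = np.hypot(vx, vy)
    return VelocitySeries(vx=vx, vy=vy, speed=speed, defined_mask=defined,
                          rate_hz=trace.rate_hz, window=w)


def robust_sigma(vel: VelocitySeries, scope_mask: np.ndarray | None = None
                 ) -> tuple[float, float]:
    """Median-based velocity dispersion per axis.

    ``sigma = sqrt(median(v**2) - median(v)**2)`` over the defined samples in
    scope.  This median estimator is insensitive to the rare fast events whose
    detection it serves.

    Parameters
    ----------
    vel
        Velocity series.
    scope_mask
        Optional boolean mask restricting the estimation scope (e.g. the
        samples of one fixation, or all fixation samples of a trial pooled).

    Raises
    ------
    DegenerateSignalError
        If either axis dispersion falls below ``SIGMA_FLOOR_DEGS`` —
        constant or duplicated position data cannot support a threshold.
    ValidationError
        If fewer than ``MIN_SIGMA_SAMPLES`` defined samples are in scope.
    """
    sel = vel.defined_mask if scope_mask is None else (vel.defined_mask & scope_mask)
    n = int(np.count_nonzero(sel))
    if n < MIN_SIGMA_SAMPLES:
        raise ValidationError(
            f"need at least {MIN_SIGMA_SAMPLES} defined velocity samples to "
            f"estimate dispersion, got {n}"
        )
    sigmas = []
    for v in (vel.vx[sel], vel.vy[sel]):
        med = np.median(v)
        med_sq = np.median(v * v)
        sigmas.append(float(np.sqrt(max(med_sq - med * med, 0.0))))
    sx, sy = sigmas
    if sx < SIGMA_FLOOR_DEGS or sy < SIGMA_FLOOR_DEGS:
        raise DegenerateSignalError(
            f"velocity dispersion degenerate (sigma_x={sx:.3g}, sigma_y={sy:.3g} "
            "deg/s); the position signal is constant or duplicated"
        )
    return sx, sy
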