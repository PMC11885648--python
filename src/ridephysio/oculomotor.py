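"""Gaze cleaning: pupil-ellipse geometry, angular conversion, validity
rules, blink detection and the final low-pass.

The validity chain mirrors a field eye-tracking pipeline: samples outside
the eyeball disk are invalid, steps faster than 500 deg/s are invalid,
invalid runs of at most 20 ms are linearly interpolated, longer runs are
measurement errors, and error runs that coincide in both eyes (within one
sample) are blinks.  Head-displacement series, already in degrees, bypass
conversion/velocity/blink handling entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from skimage.measure import EllipseModel

from .segmentation import Interval

logger = logging.getLogger(__name__)

MAX_GAP_S = 0.020
VMAX_DEG_S = 500.0


@dataclass(frozen=True)
class EllipseParams:
    """Best-fit pupil ellipse: center (px), semi-axes a >= b (px), rotation deg in [0, 180)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if not (0 <= self.rotation < 180):
            raise ValueError("rotation must lie in [0, 180)")


@dataclass(frozen=True)
class EyeGeometry:
    """Eyeball disk (center, radius, px) and camera roll (deg) from the
    horizontal eye-muscle landmark line."""

    bulbus_center: tuple[float, float]
    bulbus_radius: float
    camera_roll: float = 0.0

    def __post_init__(self) -> None:
        if self.bulbus_radius <= 0:
            raise ValueError("bulbus_radius must be positive")


@dataclass
class GazeTrace:
    """Per-eye angular trace with validity flags and error-run bookkeeping."""

    time: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    valid: np.ndarray
    rate: float
    error_runs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.time.size
        if not (self.yaw.size == self.pitch.size == self.valid.size == n):
            raise ValueError("time/yaw/pitch/valid lengths differ")

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            time=self.time.copy(),
            yaw=self.yaw.copy(),
            pitch=self.pitch.copy(),
            valid=self.valid.copy(),
            rate=self.rate,
            error_runs=list(self.error_runs),
        )


@dataclass(frozen=True)
class BlinkEvents:
    """Disjoint blink intervals [start, end) in seconds."""

    intervals: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.intervals)


class EllipseFitError(ValueError):
    pass


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Least-squares conic fit constrained to an ellipse.

    Requires >= 5 non-collinear boundary points; degenerate sets raise
    :class:`EllipseFitError`.  Circles report rotation 0 by convention.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise EllipseFitError("need at least 5 (x, y) boundary points")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise EllipseFitError("degenerate point set: ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts) or model.params is None:
            raise EllipseFitError("degenerate point set: ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("degenerate point set: ellipse fit failed")
    if a <= 0 or b <= 0:
        raise EllipseFitError("degenerate ellipse (nonpositive axis)")
    rot = np.degrees(theta)
    if b > a:
        a, b = b, a
        rot += 90.0
    rot %= 180.0
    if np.isclose(a, b, rtol=1e-6):
        rot = 0.0
    return EllipseParams(center=(float(xc), float(yc)), semi_axes=(float(a), float(b)), rotation=float(rot))


def pixels_to_degrees(
    center: tuple[float, float] | np.ndarray, geometry: EyeGeometry
) -> tuple[float, float] | tuple[np.ndarray, np.ndarray]:
    """Map pupil-center pixels to (yaw, pitch) degrees on a spherical model.

    The offset from the eyeball center is roll-corrected, then
    yaw = asin(dx/r), pitch = asin(dy/r).  Points outside the disk map to
    (nan, nan) -> sample invalid.
    """
    pt = np.asarray(center, dtype=float)
    scalar = pt.ndim == 1
    pt = np.atleast_2d(pt)
    dx = pt[:, 0] - geometry.bulbus_center[0]
    dy = pt[:, 1] - geometry.bulbus_center[1]
    roll = np.radians(geometry.camera_roll)
    c, s = np.cos(roll), np.sin(roll)
    dxr = c * dx + s * dy
    dyr = -s * dx + c * dy
    r = geometry.bulbus_radius
    inside = dxr**2 + dyr**2 <= r**2
    with np.errstate(invalid="ignore"):
        yaw = np.degrees(np.arcsin(np.clip(dxr / r, -1, 1)))
        pitch = np.degrees(np.arcsin(np.clip(dyr / r, -1, 1)))
    yaw = np.where(inside, yaw, np.nan)
    pitch = np.where(inside, pitch, np.nan)
    if scalar:
        return float(yaw[0]), float(pitch[0])
    return yaw, pitch


def velocity_filter(trace: GazeTrace, vmax: float = VMAX_DEG_S) -> GazeTrace:
    """Invalidate the later sample of any consecutive-valid pair whose
    angular speed exceeds ``vmax`` deg/s; iterate to a fixed point."""
    out = trace.copy()
    while True:
        idx = np.flatnonzero(out.valid)
        if idx.size < 2:
            break
        dyaw = np.diff(out.yaw[idx])
        dpitch = np.diff(out.pitch[idx])
        dt = np.diff(out.time[idx])
        speed = np.hypot(dyaw, dpitch) / dt
        bad = speed > vmax
        if not np.any(bad):
            break
        out.valid[idx[1:][bad]] = False
    return out


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index runs of consecutive invalid samples."""
    runs = []
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(trace: GazeTrace, max_gap: float = MAX_GAP_S) -> GazeTrace:
    """Linearly fill invalid runs no longer than ``max_gap`` seconds.

    Longer runs — and runs touching the series edge — become measurement
    errors: recorded in ``error_runs`` and left invalid.
    """
    out = trace.copy()
    period = 1.0 / out.rate
    errors = []
    for i, j in _invalid_runs(out.valid):
        duration = (j - i) * period
        at_edge = i == 0 or j == out.valid.size
        if at_edge or duration > max_gap + 1e-12:
            errors.append((float(out.time[i]), float(out.time[j - 1] + period)))
            continue
        t0, t1 = out.time[i - 1], out.time[j]
        frac = (out.time[i:j] - t0) / (t1 - t0)
        out.yaw[i:j] = out.yaw[i - 1] + frac * (out.yaw[j] - out.yaw[i - 1])
        out.pitch[i:j] = out.pitch[i - 1] + frac * (out.pitch[j] - out.pitch[i - 1])
        out.valid[i:j] = True
    out.error_runs = errors
    return out


def detect_blinks(left: GazeTrace, right: GazeTrace) -> BlinkEvents:
    """Error runs present in both eyes with matching intervals (+/- one
    sample period on each endpoint) are blinks; symmetric in eye order."""
    if not np.isclose(left.rate, right.rate):
        raise ValueError(f"mismatched rates: {left.rate} vs {right.rate}")
    tol = 1.0 / left.rate + 1e-9
    blinks = []
    used = set()
    for ls, le in left.error_runs:
        for k, (rs, re) in enumerate(right.error_runs):
            if k in used:
                continue
            if abs(ls - rs) <= tol and abs(le - re) <= tol:
                blinks.append((min(ls, rs), max(le, re)))
                used.add(k)
                break
    blinks.sort()
    return BlinkEvents(intervals=tuple(blinks))


def lowpass(trace: GazeTrace, cutoff: float | None = None, order: int = 2) -> GazeTrace:
    """Second-order Butterworth low-pass on the valid signal.

    An explicit cutoff at or above Nyquist raises; the default asks for
    60 Hz and falls back to 50 Hz with a warning when the rate cannot
    support it (e.g. 120 Hz sampling).
    """
    nyq = trace.rate / 2.0
    if cutoff is None:
        cutoff = 60.0
        if cutoff >= nyq:
            fallback = min(50.0, 0.9 * nyq)
            logger.warning(
                "low-pass cutoff 60 Hz >= Nyquist %.1f Hz; falling back to %.1f Hz",
                nyq,
                fallback,
            )
            cutoff = fallback
    elif cutoff >= nyq:
        raise ValueError(
            f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz; pass cutoff=None to use the "
            "50 Hz fallback or choose a cutoff below Nyquist"
        )
    sos = signal.butter(order, cutoff, btype="lowpass", fs=trace.rate, output="sos")
    out = trace.copy()
    # filter each contiguous valid run independently; short runs pass through
    padlen = 3 * (2 * order + 1)
    i = 0
    n = out.valid.size
    while i < n:
        if out.valid[i]:
            j = i
            while j < n and out.valid[j]:
                j += 1
            if j - i > padlen:
                out.yaw[i:j] = signal.sosfiltfilt(sos, out.yaw[i:j])
                out.pitch[i:j] = signal.sosfiltfilt(sos, out.pitch[i:j])
            i = j
        else:
            i += 1
    return out


def blink_frequency(blinks: BlinkEvents, segments: list[Interval]) -> dict[str, int]:
    """Blink count per segment; a blink belongs to the segment containing
    its start time."""
    counts = {seg.label: 0 for seg in segments}
    for start, _end in blinks.intervals:
        for seg in segments:
            if seg.contains(start):
                counts[seg.label] += 1
                break
    return counts


def clean_gaze(
    trace: GazeTrace, *, vmax: float = VMAX_DEG_S, max_gap: float = MAX_GAP_S
) -> GazeTrace:
    """Velocity filter -> gap interpolation (errors recorded) -> low-pass."""
    out = velocity_filter(trace, vmax=vmax)
    out = interpolate_gaps(out, max_gap=max_gap)
    return lowpass(out)
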