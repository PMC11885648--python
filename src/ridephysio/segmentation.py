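"""Route geometry -> time intervals.

Two schemes are produced from the same ride layout:

* a 4-segment partition of the whole ride used for the EEG indices
  (segments 1 and 3 are "smooth", 2 and 4 are "unexpected"), and
* three equal-length event windows (smooth / deer / kid) used for the
  movement and blink measures.

All intervals are half-open ``[start, end)`` in seconds from block start;
samples and events are assigned to an interval by their onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RideLayout:
    """Geometry of one ride: total duration and event positions.

    ``deer_frac`` and ``kid_frac`` are the positions of the two obstacle
    encounters as fractions of the route; ``pre_window`` is the anticipation
    interval (seconds) prepended to each encounter.
    """

    total_duration: float
    deer_frac: float = 0.5
    kid_frac: float = 0.9
    pre_window: float = 5.0

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if not (0.0 < self.deer_frac < self.kid_frac < 1.0):
            raise ValueError("require 0 < deer_frac < kid_frac < 1")
        if self.pre_window < 0:
            raise ValueError("pre_window must be nonnegative")
        if self.pre_window >= (self.kid_frac - self.deer_frac) * self.total_duration:
            raise ValueError("pre_window too large for the event spacing")

    @property
    def deer_time(self) -> float:
        return self.deer_frac * self.total_duration

    @property
    def kid_time(self) -> float:
        return self.kid_frac * self.total_duration

    def to_dict(self) -> dict:
        return {
            "total_duration_s": self.total_duration,
            "deer_frac": self.deer_frac,
            "kid_frac": self.kid_frac,
            "pre_window_s": self.pre_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RideLayout":
        return cls(
            total_duration=float(d["total_duration_s"]),
            deer_frac=float(d.get("deer_frac", 0.5)),
            kid_frac=float(d.get("kid_frac", 0.9)),
            pre_window=float(d.get("pre_window_s", 5.0)),
        )


@dataclass(frozen=True)
class Interval:
    """Half-open labeled interval [start, end) in seconds."""

    label: str
    start: float
    end: float
    tag: str = ""

    @property
    def length(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class RouteSegments:
    eeg_segments: tuple[Interval, ...]
    event_windows: tuple[Interval, ...] = field(default_factory=tuple)


def eeg_segments(layout: RideLayout) -> list[Interval]:
    """Four-segment partition of the ride anchored on the obstacle positions.

    With total duration T, deer time d, kid time k and pre-window w:
    ``[0, d-w)``, ``[d-w, 0.6 T)``, ``[0.6 T, k-w)``, ``[k-w, T)``,
    tagged smooth / unexpected / smooth / unexpected.
    """
    T = layout.total_duration
    d = layout.deer_time
    k = layout.kid_time
    w = layout.pre_window
    bounds = [0.0, d - w, 0.6 * T, k - w, T]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            raise ValueError(
                f"segment boundaries collapse: {bounds} (layout {layout})"
            )
    tags = ("smooth", "unexpected", "smooth", "unexpected")
    return [
        Interval(label=f"segment{i + 1}", start=bounds[i], end=bounds[i + 1], tag=tags[i])
        for i in range(4)
    ]


def event_windows(layout: RideLayout, window_length: float) -> list[Interval]:
    """Three equal-length windows: smooth, deer and kid.

    Deer and kid windows start ``pre_window`` seconds before their event; the
    smooth window is the interval of the same length immediately preceding
    the deer pre-window (maximally separated from both events while staying
    in the first smooth segment).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    T = layout.total_duration
    d = layout.deer_time
    k = layout.kid_time
    w = layout.pre_window
    smooth = Interval("smooth", d - w - window_length, d - w, tag="smooth")
    deer = Interval("deer", d - w, d - w + window_length, tag="unexpected")
    kid = Interval("kid", k - w, k - w + window_length, tag="unexpected")
    if smooth.start < 0:
        raise ValueError("smooth window starts before the ride; shorten window_length")
    if deer.end > kid.start:
        raise ValueError("deer and kid windows overlap; shorten window_length")
    if kid.end > T:
        raise ValueError("kid window extends past the end of the ride")
    return [smooth, deer, kid]


def assign(intervals: list[Interval], onset: float) -> str | None:
    """Label of the interval whose span contains ``onset``, else None."""
    for iv in intervals:
        if iv.contains(onset):
            return iv.label
    return None
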