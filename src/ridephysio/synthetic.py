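"""Synthetic-cohort generators with known ground truth.

Everything the downstream pipeline consumes can be generated here: dyadic
multiplicative cascades (exact multifractal fixtures), fractional Gaussian
noise by circulant embedding (monofractal control), band-structured EEG
with a controllable frontal-alpha-power asymmetry, binocular gaze traces
with scheduled blinks / monocular dropouts / saccades, cascade-modulated
head-displacement series, and a full 2-condition x 3-event cohort with
planted effects.  All randomness flows through one seeded generator per
call; nothing touches global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .segmentation import Interval, RideLayout, eeg_segments, event_windows

EEG_CHANNELS = ("F3", "F4", "FPz", "Oz")
CONDITIONS = ("human", "selfdriving")
EVENTS = ("smooth", "deer", "kid")

DEFAULT_BAND_AMPLITUDES = {"alpha": 4.0, "beta": 2.0, "gamma": 1.0}  # uV

_BAND_EDGES = {"alpha": (8.0, 12.0), "beta": (13.0, 30.0), "gamma": (30.0, 45.0)}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class CascadeSpec:
    """Two-scale multiplicative cascade: weight p, dyadic depth, seed."""

    p: float
    depth: int
    seed: int = 0
    randomize: bool = False  # shuffle left/right weight order per split

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie in (0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.depth > 24:
            raise ValueError("depth > 24 rejected (memory guard)")


@dataclass
class SyntheticEEGSpec:
    """Band-structured EEG with controllable alpha asymmetry.

    ``band_amplitudes`` maps channel -> band -> amplitude A (uV), with band
    power A^2/2 (sinusoid convention).  ``faa_target`` (log10 F4/F3 alpha
    power) overrides the alpha amplitudes of F3/F4, keeping their geometric
    mean; it may be a constant or a piecewise list of (start_s, end_s,
    target).  ``artifact_epochs`` injects 0.5 s 10 Hz bursts of the given
    amplitude.
    """

    duration: float
    rate: float = 200.0
    band_amplitudes: dict = field(default_factory=dict)
    faa_target: float | list | None = None
    artifact_epochs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rate <= 2 * 48.0:
            raise ValueError("rate must exceed 96 Hz (2 x 48 Hz)")
        for ch, bands in self.band_amplitudes.items():
            for band, amp in bands.items():
                if amp < 0:
                    raise ValueError(f"negative amplitude for {ch}/{band}")
                lo, hi = _BAND_EDGES[band]
                if hi >= self.rate / 2:
                    raise ValueError(f"band {band} outside 1-{self.rate / 2} Hz")


@dataclass(frozen=True)
class CohortSpec:
    """Planted-effect cohort: n subjects x 2 conditions x 3 events."""

    n_subjects: int
    condition_effect_faa: float = 0.0  # human minus selfdriving
    event_effect_mfsw: float = 0.0  # deer-window spectrum-width elevation
    event_effect_blink: float = 1.0  # blink-rate multiplier for event windows
    noise_sd: float = 0.0  # within-cell SD of the planted FAA values
    seed: int = 0
    subject_sd: float = 0.1
    faa_baseline: float = 0.2
    blink_rate: float = 0.35  # Hz, smooth travel
    mfsw_baseline: float = 0.45

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# fractal fixtures


def gen_binomial_cascade(spec: CascadeSpec) -> np.ndarray:
    """Measure of length 2^depth; cells are products of depth factors from
    {p, 1-p} and sum to 1.

    The canonical cascade is deterministic; with ``randomize`` the weight
    order of each split is shuffled by the seeded generator (cell values
    permuted, distribution unchanged).
    """
    rng = np.random.default_rng(spec.seed)
    measure = np.array([1.0])
    for _ in range(spec.depth):
        left = np.full(measure.size, spec.p)
        if spec.randomize:
            flip = rng.random(measure.size) < 0.5
            left = np.where(flip, 1.0 - spec.p, spec.p)
        out = np.empty(measure.size * 2)
        out[0::2] = measure * left
        out[1::2] = measure * (1.0 - left)
        measure = out
    return measure


def gen_fgn(hurst: float, n: int, seed: int = 0) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via exact circulant embedding."""
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # clip tiny negative rounding noise
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z)
    return x.real[:n]


def cascade_modulated_noise(
    spec: CascadeSpec,
    n: int,
    seed: int | None = None,
    mode: str = "variance",
) -> np.ndarray:
    """Gaussian noise whose local scale follows the cascade cells.

    The 2^depth cells act as local variance (``mode='variance'``) or local
    amplitude (``mode='amplitude'``) of unit white noise, normalized so the
    average variance is 1; the cell pattern is tiled/cropped to length n.
    This is the time-series export of the cascade for pipeline-level tests.
    """
    cells = gen_binomial_cascade(spec)
    scale = cells * cells.size  # mean 1
    if mode == "variance":
        sigma = np.sqrt(scale)
    elif mode == "amplitude":
        sigma = scale
    else:
        raise ValueError("mode must be 'variance' or 'amplitude'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    reps = int(np.ceil(n / sigma.size))
    sig = np.tile(sigma, reps)[:n]
    return rng.standard_normal(n) * sig


# ---------------------------------------------------------------------------
# EEG


def _band_carrier(rng: np.random.Generator, n: int, rate: float, band: str) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier (filtered white noise)."""
    lo, hi = _BAND_EDGES[band]
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _piecewise_faa(faa_target, duration: float) -> list[tuple[float, float, float]]:
    if faa_target is None:
        return []
    if np.isscalar(faa_target):
        return [(0.0, duration, float(faa_target))]
    return [(float(a), float(b), float(v)) for a, b, v in faa_target]


def gen_synthetic_eeg(spec: SyntheticEEGSpec):
    """Recording with per-band carriers at requested amplitudes.

    Carriers are renormalized to exact target RMS (A / sqrt(2)) — per
    region when ``faa_target`` is piecewise — so realized Welch band powers
    track the request closely.  Artifact bursts are added last.
    """
    from .eeg import Recording  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    amps = {
        ch: {**DEFAULT_BAND_AMPLITUDES, **spec.band_amplitudes.get(ch, {})}
        for ch in EEG_CHANNELS
    }

    regions = _piecewise_faa(spec.faa_target, spec.duration)

    values = np.zeros((len(EEG_CHANNELS), n))
    for ci, ch in enumerate(EEG_CHANNELS):
        for band in ("alpha", "beta", "gamma"):
            amp = amps[ch][band]
            if amp == 0:
                continue
            carrier = _band_carrier(rng, n, spec.rate, band)
            target_rms = amp / np.sqrt(2.0)
            if band == "alpha" and ch in ("F3", "F4") and regions:
                base = np.sqrt(amps["F3"]["alpha"] * amps["F4"]["alpha"]) / np.sqrt(2.0)
                scaled = carrier * target_rms
                for a, b, faa_val in regions:
                    i0, i1 = int(round(a * spec.rate)), int(round(b * spec.rate))
                    i1 = min(i1, n)
                    if i1 <= i0:
                        continue
                    seg = carrier[i0:i1]
                    sd = seg.std()
                    ratio = 10.0 ** (faa_val / 4.0)  # power ratio^(1/4) per channel
                    rms = base * (ratio if ch == "F4" else 1.0 / ratio)
                    scaled[i0:i1] = seg / (sd if sd > 0 else 1.0) * rms
                values[ci] += scaled
            else:
                values[ci] += carrier * target_rms

    for onset, amp in spec.artifact_epochs:
        i0 = int(round(onset * spec.rate))
        i1 = min(i0 + int(round(0.5 * spec.rate)), n)
        burst = amp * np.sin(2 * np.pi * 10.0 * t[i0:i1])
        values[:, i0:i1] += burst[None, :]

    return Recording(values=values, rate=spec.rate, channel_names=EEG_CHANNELS)


# ---------------------------------------------------------------------------
# gaze


@dataclass
class RawGaze:
    """Raw per-eye angular coordinates with validity flags."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float


def _check_disjoint(events: list[tuple[float, float]]) -> None:
    ordered = sorted(events)
    for (s1, e1), (s2, _e2) in zip(ordered[:-1], ordered[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping scheduled events at {s2:.3f}s")


def gen_gaze_trace(
    duration: float,
    rate: float = 120.0,
    blink_schedule: list[tuple[float, float]] | None = None,
    saccade_spec: list[tuple[float, float, float]] | None = None,
    monocular_dropouts: list[tuple[str, float, float]] | None = None,
    seed: int = 0,
    wander_sd: float = 0.05,
    jitter: np.ndarray | None = None,
) -> tuple[RawGaze, RawGaze]:
    """Left/right raw gaze with scheduled blinks, saccades and dropouts.

    ``blink_schedule``: (start_s, duration_s) simultaneous binocular
    dropouts.  ``saccade_spec``: (time_s, dx_deg, dy_deg) instantaneous
    steps (dx of 6 deg at 120 Hz means a 720 deg/s step).
    ``monocular_dropouts``: ("left"|"right", start_s, duration_s).
    ``jitter`` adds a shared extra displacement series (e.g. cascade
    modulated) to both eyes.  Overlapping scheduled events raise.
    """
    blink_schedule = blink_schedule or []
    saccade_spec = saccade_spec or []
    monocular_dropouts = monocular_dropouts or []
    spans = [(s, s + d) for s, d in blink_schedule]
    spans += [(s, s + d) for _eye, s, d in monocular_dropouts]
    _check_disjoint(spans)

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    # slow fixation wander: heavily smoothed noise, per-axis
    def wander() -> np.ndarray:
        w = np.cumsum(rng.standard_normal(n)) / np.sqrt(rate)
        sos = signal.butter(2, 1.0, btype="lowpass", fs=rate, output="sos")
        w = signal.sosfiltfilt(sos, w)
        sd = w.std()
        return w / (sd if sd > 0 else 1.0) * wander_sd * 10

    x = wander()
    y = wander()
    for when, dx, dy in saccade_spec:
        i = int(round(when * rate))
        x[i:] += dx
        y[i:] += dy
    if jitter is not None:
        j = np.asarray(jitter, dtype=float)
        x = x + j[:n] if j.size >= n else x
    x_noise = rng.standard_normal((2, n)) * wander_sd
    y_noise = rng.standard_normal((2, n)) * wander_sd

    eyes = []
    for k, eye in enumerate(("left", "right")):
        valid = np.ones(n, dtype=bool)
        for start, dur in blink_schedule:
            i0, i1 = int(round(start * rate)), int(round((start + dur) * rate))
            valid[i0:i1] = False
        for which, start, dur in monocular_dropouts:
            if which == eye:
                i0, i1 = int(round(start * rate)), int(round((start + dur) * rate))
                valid[i0:i1] = False
        ex = x + x_noise[k]
        ey = y + y_noise[k]
        ex[~valid] = np.nan
        ey[~valid] = np.nan
        eyes.append(RawGaze(time=t, x=ex, y=ey, valid=valid, rate=rate))
    return eyes[0], eyes[1]


# ---------------------------------------------------------------------------
# head movement


def gen_head_series(
    duration: float,
    rate: float,
    windows: list[Interval],
    window_p: dict[str, float],
    base_p: float = 0.45,
    seed: int = 0,
    scale_deg: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement series (time, position deg) whose fluctuation structure
    inside each labeled window follows a cascade with that window's p."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    incr = cascade_modulated_noise(
        CascadeSpec(p=base_p, depth=12, seed=int(rng.integers(2**31))), n,
        seed=int(rng.integers(2**31)),
    )
    for win in windows:
        i0, i1 = int(round(win.start * rate)), int(round(win.end * rate))
        i1 = min(i1, n)
        p = window_p.get(win.label, base_p)
        depth = max(6, int(np.floor(np.log2(max(i1 - i0, 64)))))
        seg = cascade_modulated_noise(
            CascadeSpec(p=p, depth=min(depth, 14), seed=int(rng.integers(2**31))),
            i1 - i0,
            seed=int(rng.integers(2**31)),
        )
        incr[i0:i1] = seg
    pos = np.cumsum(incr) * scale_deg / np.sqrt(rate)
    return t, pos


def _width_to_p(width: float) -> float:
    """Invert the asymptotic cascade width log2((1-p)/p) -> p, clipped."""
    w = max(width, 0.02)
    p = 1.0 / (1.0 + 2.0**w)
    return float(np.clip(p, 0.05, 0.499))


def _blink_times(
    rng: np.random.Generator,
    windows: list[Interval],
    base_rate: float,
    multipliers: dict[str, float],
    blink_dur: float = 0.1,
    min_sep: float = 0.4,
) -> list[tuple[float, float]]:
    """Blink (start, duration) schedule with per-window rates."""
    out = []
    for win in windows:
        rate = base_rate * multipliers.get(win.label, 1.0)
        t = win.start + min_sep * rng.random()
        while t + blink_dur < win.end:
            out.append((float(t), blink_dur))
            gap = max(min_sep, rng.exponential(1.0 / rate) if rate > 0 else np.inf)
            t += blink_dur + gap
    return out


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectBundle:
    subject: str
    condition: str
    eeg: "object"  # Recording
    gaze_left: RawGaze
    gaze_right: RawGaze
    head_t: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    blink_schedule: list


@dataclass
class Cohort:
    layout: RideLayout
    window_length: float
    bundles: list[SubjectBundle]
    truth: pd.DataFrame  # planted cell-level values (subject, condition, event, faa, mfsw, blink_rate)


def gen_cohort(
    spec: CohortSpec,
    layout: RideLayout,
    window_length: float = 20.0,
    head_rate: float = 30.0,
    gaze_rate: float = 120.0,
    modalities: tuple[str, ...] = ("eeg", "gaze", "head"),
) -> Cohort:
    """Full synthetic cohort realizing the planted effects.

    The planted per-cell FAA targets (condition effect +/- half the
    human-minus-selfdriving difference, subject intercepts, within-cell
    noise) are drawn first and stored in ``truth``; signals are then
    synthesized to realize them.  The deer event window gets the planted
    spectrum-width elevation; deer and kid windows get the blink-rate
    multiplier.
    """
    rng = np.random.default_rng(spec.seed)
    segs = eeg_segments(layout)
    windows = event_windows(layout, window_length)
    truth_rows = []
    bundles = []
    seg_by_event = {"smooth": ["segment1", "segment3"], "deer": ["segment2"], "kid": ["segment4"]}

    for s in range(spec.n_subjects):
        subject = f"S{s + 1:03d}"
        icpt = rng.normal(0.0, spec.subject_sd)
        icpt_w = rng.normal(0.0, spec.subject_sd * 0.2)
        for cond in CONDITIONS:
            cond_shift = (
                +spec.condition_effect_faa / 2.0
                if cond == "human"
                else -spec.condition_effect_faa / 2.0
            )
            faa_cells = {}
            mfsw_cells = {}
            for ev in EVENTS:
                faa_cells[ev] = (
                    spec.faa_baseline + icpt + cond_shift + rng.normal(0.0, spec.noise_sd)
                )
                mfsw_cells[ev] = max(
                    spec.mfsw_baseline
                    + icpt_w
                    + (spec.event_effect_mfsw if ev == "deer" else 0.0)
                    + rng.normal(0.0, spec.noise_sd * 0.2),
                    0.05,
                )
                truth_rows.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "event": ev,
                        "faa": faa_cells[ev],
                        "mfsw": mfsw_cells[ev],
                        "blink_rate": spec.blink_rate
                        * (spec.event_effect_blink if ev != "smooth" else 1.0),
                    }
                )

            # piecewise FAA: each EEG segment gets its event's planted value
            pieces = []
            for ev, seg_names in seg_by_event.items():
                for seg in segs:
                    if seg.label in seg_names:
                        pieces.append((seg.start, seg.end, faa_cells[ev]))
            eeg = None
            if "eeg" in modalities:
                eeg_spec = SyntheticEEGSpec(
                    duration=layout.total_duration,
                    faa_target=sorted(pieces),
                    seed=int(rng.integers(2**31)),
                )
                eeg = gen_synthetic_eeg(eeg_spec)

            window_p = {w.label: _width_to_p(mfsw_cells[w.label]) for w in windows}
            mult = {
                "deer": spec.event_effect_blink,
                "kid": spec.event_effect_blink,
                "smooth": 1.0,
            }
            left = right = None
            blink_schedule = []
            if "gaze" in modalities:
                blink_schedule = _blink_times(rng, windows, spec.blink_rate, mult)
                n_gaze = int(round(layout.total_duration * gaze_rate))
                jitter = gen_head_series(
                    layout.total_duration,
                    gaze_rate,
                    windows,
                    window_p,
                    seed=int(rng.integers(2**31)),
                    scale_deg=0.3,
                )[1][:n_gaze]
                # jitter steps must stay below the 500 deg/s validity ceiling
                # (4.2 deg/sample at 120 Hz) or the velocity filter censors
                # exactly the bursts that carry the planted multifractality
                left, right = gen_gaze_trace(
                    layout.total_duration,
                    rate=gaze_rate,
                    blink_schedule=blink_schedule,
                    seed=int(rng.integers(2**31)),
                    jitter=np.diff(jitter, prepend=jitter[0]) * 4.5,
                    wander_sd=0.008,
                )
            head_t = head_x = head_y = None
            if "head" in modalities:
                head_t, head_x = gen_head_series(
                    layout.total_duration, head_rate, windows, window_p,
                    seed=int(rng.integers(2**31)),
                )
                _, head_y = gen_head_series(
                    layout.total_duration, head_rate, windows, window_p,
                    seed=int(rng.integers(2**31)),
                )
            bundles.append(
                SubjectBundle(
                    subject=subject,
                    condition=cond,
                    eeg=eeg,
                    gaze_left=left,
                    gaze_right=right,
                    head_t=head_t,
                    head_x=head_x,
                    head_y=head_y,
                    blink_schedule=blink_schedule,
                )
            )
    truth = pd.DataFrame(truth_rows)
    return Cohort(layout=layout, window_length=window_length, bundles=bundles, truth=truth)


# ---------------------------------------------------------------------------
# fixture export


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """One directory per subject x condition with the CSV/JSON fixture files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "layout.json").write_text(
        json.dumps({**cohort.layout.to_dict(), "window_length_s": cohort.window_length}, indent=2)
    )
    cohort.truth.to_csv(out / "truth.csv", index=False)
    for b in cohort.bundles:
        d = out / f"{b.subject}_{b.condition}"
        d.mkdir(exist_ok=True)
        if b.eeg is not None:
            b.eeg.to_frame().to_csv(d / "eeg.csv", index=False)
        for eye, g in (("left", b.gaze_left), ("right", b.gaze_right)):
            if g is not None:
                pd.DataFrame(
                    {"time_s": g.time, "x": g.x, "y": g.y, "valid": g.valid.astype(int)}
                ).to_csv(d / f"gaze_{eye}.csv", index=False)
        if b.head_t is not None:
            pd.DataFrame(
                {"time_s": b.head_t, "x_deg": b.head_x, "y_deg": b.head_y}
            ).to_csv(d / "head.csv", index=False)
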