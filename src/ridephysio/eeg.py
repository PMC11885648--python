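"""EEG preprocessing and per-segment affect/arousal indices.

Chain: band-pass filter (7-48 Hz, 9th-order Butterworth, zero-phase) ->
2 s epochs with 1 s overlap -> +/-100 uV amplitude rejection -> Welch band
powers (alpha 8-12, beta 13-30, gamma 30-45 Hz) -> per-epoch frontal alpha
asymmetry (log10 F4 - log10 F3) and arousal ((beta+gamma)/alpha at the
F3/F4 mean) -> 3-SD within-participant outlier removal -> segment means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .segmentation import Interval, assign

BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

DEFAULT_CHANNELS = ("F3", "F4", "FPz", "Oz")


@dataclass
class Recording:
    """One uniformly sampled multichannel block (values in uV)."""

    values: np.ndarray  # channel x sample
    rate: float
    channel_names: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names length must match value rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channel_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        t = self.t0 + np.arange(self.n_samples) / self.rate
        df = pd.DataFrame({"time_s": t})
        for i, ch in enumerate(self.channel_names):
            df[ch] = self.values[i]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float | None = None) -> "Recording":
        t = df["time_s"].to_numpy(dtype=float)
        if rate is None:
            if len(t) < 2:
                raise ValueError("cannot infer rate from fewer than 2 samples")
            rate = 1.0 / np.median(np.diff(t))
        channels = [c for c in df.columns if c != "time_s"]
        values = np.vstack([df[c].to_numpy(dtype=float) for c in channels])
        return cls(values=values, rate=float(round(rate, 6)), channel_names=tuple(channels), t0=float(t[0]))


@dataclass
class EpochSet:
    """Fixed-length overlapping windows with a retention mask."""

    epochs: np.ndarray  # epoch x channel x sample
    onsets: np.ndarray  # seconds
    rate: float
    channel_names: tuple[str, ...]
    epoch_length: float = 2.0
    step: float = 1.0
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.epochs.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def bandpass(
    recording: Recording, low: float = 7.0, high: float = 48.0, order: int = 9
) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = recording.rate / 2.0
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.values, axis=1)
    return Recording(
        values=filtered,
        rate=recording.rate,
        channel_names=recording.channel_names,
        t0=recording.t0,
    )


def make_epochs(recording: Recording, length: float = 2.0, step: float = 1.0) -> EpochSet:
    """Cut overlapping epochs; count = floor((N-L)/S)+1, partial tail dropped."""
    L = int(round(length * recording.rate))
    S = int(round(step * recording.rate))
    N = recording.n_samples
    if N < L:
        raise ValueError(f"recording shorter ({N} samples) than epoch length ({L})")
    n_epochs = (N - L) // S + 1
    starts = np.arange(n_epochs) * S
    idx = starts[:, None] + np.arange(L)[None, :]
    epochs = recording.values[:, idx].transpose(1, 0, 2)
    onsets = recording.t0 + starts / recording.rate
    return EpochSet(
        epochs=epochs,
        onsets=onsets,
        rate=recording.rate,
        channel_names=recording.channel_names,
        epoch_length=length,
        step=step,
    )


def reject_amplitude(epochs: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Drop epochs whose signal leaves [-threshold, +threshold] uV on any channel."""
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    retained = epochs.retained & (peak <= threshold)
    return EpochSet(
        epochs=epochs.epochs,
        onsets=epochs.onsets,
        rate=epochs.rate,
        channel_names=epochs.channel_names,
        epoch_length=epochs.epoch_length,
        step=epochs.step,
        retained=retained,
    )


def band_power(
    x: np.ndarray, rate: float, band: tuple[float, float] | str, *, nperseg: float = 1.0
) -> np.ndarray:
    """Integrated Welch PSD over a closed frequency band (uV^2).

    ``x`` may be 1-D (one epoch channel) or N-D with samples on the last
    axis; the band integral is returned per leading index.  Welch uses
    Hann windows of ``nperseg`` seconds with 50% overlap.
    """
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValueError(f"band {band} outside (0, {rate / 2}) Hz")
    nps = int(round(nperseg * rate))
    x = np.asarray(x, dtype=float)
    nps = min(nps, x.shape[-1])
    freqs, psd = signal.welch(
        x, fs=rate, window="hann", nperseg=nps, noverlap=nps // 2, axis=-1
    )
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        raise ValueError(f"no frequency bins fall inside band {band}")
    df = freqs[1] - freqs[0]
    return psd[..., in_band].sum(axis=-1) * df


def faa(alpha_f4: float | np.ndarray, alpha_f3: float | np.ndarray) -> float | np.ndarray:
    """Frontal alpha asymmetry: log10 alpha power F4 minus F3.

    Nonpositive powers yield NaN (epoch flagged invalid downstream).
    """
    p4 = np.asarray(alpha_f4, dtype=float)
    p3 = np.asarray(alpha_f3, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((p4 > 0) & (p3 > 0), np.log10(np.where(p4 > 0, p4, 1.0)) - np.log10(np.where(p3 > 0, p3, 1.0)), np.nan)
    return float(out) if out.ndim == 0 else out


def arousal(
    alpha_f3, alpha_f4, beta_f3, beta_f4, gamma_f3, gamma_f4
) -> float | np.ndarray:
    """(mean beta + mean gamma) / mean alpha over F3/F4; scale-invariant."""
    a = (np.asarray(alpha_f3, float) + np.asarray(alpha_f4, float)) / 2.0
    b = (np.asarray(beta_f3, float) + np.asarray(beta_f4, float)) / 2.0
    g = (np.asarray(gamma_f3, float) + np.asarray(gamma_f4, float)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(a > 0, (b + g) / np.where(a > 0, a, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def remove_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep-mask: drop values >= k SDs from the mean (single pass).

    Mean and SD (ddof=1) are computed once over the finite values; a zero
    SD keeps everything.  NaNs are always dropped.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    keep = finite.copy()
    vals = x[finite]
    if vals.size < 2:
        return keep
    sd = vals.std(ddof=1)
    if sd == 0:
        return keep
    z = np.abs(x - vals.mean()) / sd
    keep[finite] = z[finite] < k
    return keep


def epoch_features(epochs: EpochSet) -> pd.DataFrame:
    """Per-epoch FAA and arousal for all epochs (retained flag included)."""
    i3 = epochs.channel_names.index("F3")
    i4 = epochs.channel_names.index("F4")
    f3 = epochs.epochs[:, i3, :]
    f4 = epochs.epochs[:, i4, :]
    powers = {
        (band, ch): band_power(x, epochs.rate, band)
        for band in BANDS
        for ch, x in (("F3", f3), ("F4", f4))
    }
    faa_vals = faa(powers[("alpha", "F4")], powers[("alpha", "F3")])
    arousal_vals = arousal(
        powers[("alpha", "F3")], powers[("alpha", "F4")],
        powers[("beta", "F3")], powers[("beta", "F4")],
        powers[("gamma", "F3")], powers[("gamma", "F4")],
    )
    return pd.DataFrame(
        {
            "epoch_onset_s": epochs.onsets,
            "faa": faa_vals,
            "arousal": arousal_vals,
            "retained": epochs.retained,
        }
    )


def segment_means(
    features: pd.DataFrame,
    segments: list[Interval],
    measure: str,
    k: float = 3.0,
) -> pd.DataFrame:
    """Mean of retained, non-outlier epoch values per route segment.

    Outlier removal (k-SD rule) runs over this participant's retained epochs
    for the given measure before averaging.  Empty segments yield NaN.
    """
    df = features[features["retained"]].copy()
    keep = remove_outliers(df[measure].to_numpy(), k=k)
    df = df[keep]
    rows = []
    for seg in segments:
        in_seg = df[(df["epoch_onset_s"] >= seg.start) & (df["epoch_onset_s"] < seg.end)]
        rows.append(
            {
                "segment": seg.label,
                "tag": seg.tag,
                "n_epochs": len(in_seg),
                "mean": in_seg[measure].mean() if len(in_seg) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def process_recording(
    recording: Recording,
    segments: list[Interval],
    *,
    low: float = 7.0,
    high: float = 48.0,
    order: int = 9,
    threshold: float = 100.0,
    pre_filter_hook=None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full EEG chain on one recording.

    Returns the per-epoch feature table and per-measure segment-mean tables.
    ``pre_filter_hook`` is an optional callable Recording -> Recording run
    before filtering (slot for an external artifact-correction step).
    """
    if pre_filter_hook is not None:
        recording = pre_filter_hook(recording)
    filtered = bandpass(recording, low=low, high=high, order=order)
    epochs = make_epochs(filtered)
    epochs = reject_amplitude(epochs, threshold=threshold)
    feats = epoch_features(epochs)
    seg_tables = {m: segment_means(feats, segments, m) for m in ("faa", "arousal")}
    return feats, seg_tables
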