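"""End-to-end orchestration: cohort -> per-cell measures -> statistics.

Stages exchange long-format CSV tables (subject, condition, event, measure,
value) so each stage is independently testable from fixtures.  A run is
deterministic given the seed and emits a manifest (config hash, versions,
seed) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eeg import Recording, epoch_features, bandpass, make_epochs, reject_amplitude, remove_outliers
from .multifractal import DegenerateSeriesError, MFConfig, chhabra_jensen
from .oculomotor import (
    GazeTrace,
    blink_frequency,
    detect_blinks,
    interpolate_gaps,
    lowpass,
    velocity_filter,
)
from .segmentation import Interval, RideLayout, eeg_segments, event_windows
from .stats import ci95, rm_anova, tukey_posthoc
from .synthetic import Cohort, CohortSpec, RawGaze, SubjectBundle, gen_cohort

logger = logging.getLogger(__name__)

SEG_BY_EVENT = {"smooth": ("segment1", "segment3"), "deer": ("segment2",), "kid": ("segment4",)}

EEG_MEASURES = ("faa", "arousal")
GAZE_MEASURES = ("mfsw_eye_left", "mfsw_eye_right")
HEAD_MEASURES = ("mfsw_head_x", "mfsw_head_y")
ALL_MEASURES = EEG_MEASURES + GAZE_MEASURES + HEAD_MEASURES + ("blink",)


@dataclass
class RunConfig:
    layout: RideLayout
    window_length: float = 20.0
    cohort: CohortSpec | None = None  # synthetic input
    input_dir: Path | None = None  # or pre-written fixture bundles
    measures: tuple[str, ...] = ALL_MEASURES
    mf_config: MFConfig = field(default_factory=MFConfig)
    seed: int = 0
    out_dir: Path = Path("ridephysio_out")

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            raise ValueError("need either a synthetic cohort spec or an input directory")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    def to_dict(self) -> dict:
        d = {
            "layout": self.layout.to_dict(),
            "window_length_s": self.window_length,
            "measures": list(self.measures),
            "seed": self.seed,
        }
        if self.cohort is not None:
            d["cohort"] = {
                "n_subjects": self.cohort.n_subjects,
                "condition_effect_faa": self.cohort.condition_effect_faa,
                "event_effect_mfsw": self.cohort.event_effect_mfsw,
                "event_effect_blink": self.cohort.event_effect_blink,
                "noise_sd": self.cohort.noise_sd,
                "seed": self.cohort.seed,
            }
        if self.input_dir is not None:
            d["input_dir"] = str(self.input_dir)
        return d


# ---------------------------------------------------------------------------
# per-recording measure extraction


def eeg_event_cells(recording: Recording, layout: RideLayout) -> dict[str, dict[str, float]]:
    """FAA and arousal per route event for one recording.

    Smooth pools the retained, non-outlier epochs of both smooth segments;
    deer and kid use the epochs of their pre-event segment.
    """
    segs = eeg_segments(layout)
    filtered = bandpass(recording)
    epochs = reject_amplitude(make_epochs(filtered))
    feats = epoch_features(epochs)
    out: dict[str, dict[str, float]] = {m: {} for m in EEG_MEASURES}
    seg_spans = {s.label: s for s in segs}
    for measure in EEG_MEASURES:
        kept = feats[feats["retained"]].copy()
        keep = remove_outliers(kept[measure].to_numpy())
        kept = kept[keep]
        for event, seg_names in SEG_BY_EVENT.items():
            sel = np.zeros(len(kept), dtype=bool)
            for name in seg_names:
                seg = seg_spans[name]
                sel |= (kept["epoch_onset_s"] >= seg.start).to_numpy() & (
                    kept["epoch_onset_s"] < seg.end
                ).to_numpy()
            vals = kept.loc[sel, measure]
            out[measure][event] = float(vals.mean()) if len(vals) else float("nan")
    return out


def _window_slice(t: np.ndarray, win: Interval) -> np.ndarray:
    return (t >= win.start) & (t < win.end)


def _mf_width_of_window(x: np.ndarray, config: MFConfig) -> float:
    try:
        return chhabra_jensen(x, config).width
    except (DegenerateSeriesError, ValueError):
        return float("nan")


def raw_to_trace(g: RawGaze) -> GazeTrace:
    return GazeTrace(
        time=g.time, yaw=np.nan_to_num(g.x), pitch=np.nan_to_num(g.y), valid=g.valid, rate=g.rate
    )


def gaze_event_cells(
    left: RawGaze,
    right: RawGaze,
    layout: RideLayout,
    window_length: float,
    mf_config: MFConfig,
) -> tuple[dict[str, dict[str, float]], dict[str, int]]:
    """Per-event spectrum widths for each eye plus blink counts.

    Cleaning: velocity filter, gap interpolation (errors recorded), blink
    detection on matching binocular error runs, final low-pass.  Within a
    window the residual invalid samples are linearly bridged before the
    fluctuation measure is built.
    """
    windows = event_windows(layout, window_length)
    cleaned = {}
    for eye, raw in (("left", left), ("right", right)):
        tr = velocity_filter(raw_to_trace(raw))
        tr = interpolate_gaps(tr)
        cleaned[eye] = tr
    blinks = detect_blinks(cleaned["left"], cleaned["right"])
    counts = blink_frequency(blinks, windows)

    widths: dict[str, dict[str, float]] = {}
    for eye, tr in cleaned.items():
        tr = lowpass(tr)
        cells = {}
        for win in windows:
            sel = _window_slice(tr.time, win)
            yaw, pitch, valid = tr.yaw[sel], tr.pitch[sel], tr.valid[sel]
            if valid.sum() < 64:
                cells[win.label] = float("nan")
                continue
            yaw = _bridge_invalid(yaw, valid)
            pitch = _bridge_invalid(pitch, valid)
            steps = np.hypot(np.diff(yaw), np.diff(pitch))
            cells[win.label] = _mf_width_of_window(np.concatenate([[0.0], np.cumsum(steps)]), mf_config)
        widths[f"mfsw_eye_{eye}"] = cells
    return widths, counts


def _bridge_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return x
    idx = np.arange(x.size)
    good = np.flatnonzero(valid)
    return np.interp(idx, good, x[good])


def head_event_cells(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    layout: RideLayout,
    window_length: float,
    mf_config: MFConfig,
) -> dict[str, dict[str, float]]:
    """Per-event spectrum widths of the head displacement planes."""
    windows = event_windows(layout, window_length)
    out = {}
    for name, series in (("mfsw_head_x", x), ("mfsw_head_y", y)):
        cells = {}
        for win in windows:
            sel = _window_slice(t, win)
            cells[win.label] = _mf_width_of_window(series[sel], mf_config)
        out[name] = cells
    return out


# ---------------------------------------------------------------------------
# cohort-level measures


def load_cohort(input_dir: Path) -> Cohort:
    """Read fixture bundles written by :func:`ridephysio.synthetic.write_cohort`."""
    input_dir = Path(input_dir)
    meta = json.loads((input_dir / "layout.json").read_text())
    layout = RideLayout.from_dict(meta)
    window_length = float(meta.get("window_length_s", 20.0))
    truth_path = input_dir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    bundles = []
    for d in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        subject, _, condition = d.name.rpartition("_")
        eeg_path = d / "eeg.csv"
        eeg = Recording.from_frame(pd.read_csv(eeg_path)) if eeg_path.exists() else None
        gaze = {}
        for eye in ("left", "right"):
            path = d / f"gaze_{eye}.csv"
            if path.exists():
                g = pd.read_csv(path)
                gaze[eye] = RawGaze(
                    time=g["time_s"].to_numpy(),
                    x=g["x"].to_numpy(),
                    y=g["y"].to_numpy(),
                    valid=g["valid"].to_numpy().astype(bool),
                    rate=round(1.0 / np.median(np.diff(g["time_s"].to_numpy())), 3),
                )
        head_path = d / "head.csv"
        if head_path.exists():
            h = pd.read_csv(head_path)
            head_t, head_x, head_y = (
                h["time_s"].to_numpy(),
                h["x_deg"].to_numpy(),
                h["y_deg"].to_numpy(),
            )
        else:
            head_t = head_x = head_y = None
        bundles.append(
            SubjectBundle(
                subject=subject,
                condition=condition,
                eeg=eeg,
                gaze_left=gaze.get("left"),
                gaze_right=gaze.get("right"),
                head_t=head_t,
                head_x=head_x,
                head_y=head_y,
                blink_schedule=[],
            )
        )
    return Cohort(layout=layout, window_length=window_length, bundles=bundles, truth=truth)


def cohort_measures(
    cohort: Cohort,
    measures: tuple[str, ...] = ALL_MEASURES,
    mf_config: MFConfig | None = None,
) -> pd.DataFrame:
    """Long-format measure table for a cohort (subject, condition, event,
    measure, value).  Subjects missing a modality are flagged and skipped
    for that modality only."""
    mf_config = mf_config or MFConfig()
    rows = []
    for b in cohort.bundles:
        per_measure: dict[str, dict[str, float]] = {}
        if any(m in measures for m in EEG_MEASURES):
            if b.eeg is not None:
                per_measure.update(eeg_event_cells(b.eeg, cohort.layout))
            else:
                logger.warning("%s/%s: EEG missing", b.subject, b.condition)
        want_gaze = any(m in measures for m in GAZE_MEASURES) or "blink" in measures
        if want_gaze:
            if b.gaze_left is not None and b.gaze_right is not None:
                widths, counts = gaze_event_cells(
                    b.gaze_left, b.gaze_right, cohort.layout, cohort.window_length, mf_config
                )
                per_measure.update(widths)
                if "blink" in measures:
                    per_measure["blink"] = {k: float(v) for k, v in counts.items()}
            else:
                logger.warning("%s/%s: gaze missing", b.subject, b.condition)
        if any(m in measures for m in HEAD_MEASURES):
            if b.head_t is not None:
                per_measure.update(
                    head_event_cells(
                        b.head_t, b.head_x, b.head_y, cohort.layout, cohort.window_length, mf_config
                    )
                )
            else:
                logger.warning("%s/%s: head series missing", b.subject, b.condition)
        for measure, cells in per_measure.items():
            if measure not in measures:
                continue
            for event, value in cells.items():
                rows.append(
                    {
                        "subject": b.subject,
                        "condition": b.condition,
                        "event": event,
                        "measure": measure,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics and summaries


def analyze_measures(measure_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA + event post hocs for every measure in a long table."""
    anova_rows = []
    posthoc_rows = []
    for measure, sub in measure_table.groupby("measure"):
        try:
            res = rm_anova(sub)
        except ValueError as exc:
            logger.warning("measure %s skipped: %s", measure, exc)
            continue
        af = res.to_frame()
        af.insert(0, "measure", measure)
        af["n_subjects"] = res.n_subjects
        anova_rows.append(af)
        ph = tukey_posthoc(sub, "event")
        ph.insert(0, "measure", measure)
        posthoc_rows.append(ph)
    anova = pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()
    posthoc = pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows else pd.DataFrame()
    return anova, posthoc


def summarize(measure_table: pd.DataFrame) -> pd.DataFrame:
    """Figure-style table: per measure x condition x event mean and 95% CI."""
    rows = []
    for (measure, cond, event), sub in measure_table.groupby(
        ["measure", "condition", "event"]
    ):
        vals = sub["value"].to_numpy()
        vals = vals[np.isfinite(vals)]
        mean, hw = ci95(vals)
        rows.append(
            {
                "measure": measure,
                "condition": cond,
                "event": event,
                "n": vals.size,
                "mean": mean,
                "ci95_halfwidth": hw,
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write all output tables + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        cohort = load_cohort(config.input_dir)
    else:
        cohort = gen_cohort(config.cohort, config.layout, window_length=config.window_length)
    table = cohort_measures(cohort, measures=config.measures, mf_config=config.mf_config)
    if table.empty:
        raise RuntimeError("pipeline produced an empty measure table")
    anova, posthoc = analyze_measures(table)
    summary = summarize(table)
    table.to_csv(out / "measures.csv", index=False)
    anova.to_csv(out / "anova.csv", index=False)
    posthoc.to_csv(out / "posthoc.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "version": __version__,
        "seed": config.seed,
        "n_measure_rows": int(len(table)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "measures": table,
        "anova": anova,
        "posthoc": posthoc,
        "summary": summary,
        "manifest": manifest,
    }
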