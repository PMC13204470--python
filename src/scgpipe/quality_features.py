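"""45 s window extraction, SQI screening and feature vector construction.

Each cuff measurement at time t0 defines one sample window: the 45 s of
signal immediately preceding it. Windows are normalized (zero mean, unit
SD), run through the beat pipeline, screened by a signal quality index
(SQI, threshold 0.7), and reduced to a fixed-length feature vector:
heart rate, per-beat intensity/dynamics aggregates (RMS, peak-to-peak,
maximum upstroke slope — mean and SD each) and template amplitudes read
at 0.1, 0.2, 0.3 and 0.4 s after the beat anchor.

The SQI is a reconstruction: an equally weighted geometric mean of three
sub-scores in [0, 1] — mean beat-vs-template correlation, RR regularity
exp(−CV(RR)/c) and amplitude stability exp(−CV(p2p)/c), with c = 0.5.
The screening threshold is kept at 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import beat_pipeline as bp
from .synth import BPRecord

WINDOW_DURATION_S = 45.0
SQI_THRESHOLD = 0.7

FEATURE_NAMES = (
    "hr_bpm",
    "rms_mean",
    "rms_sd",
    "p2p_mean",
    "p2p_sd",
    "upstroke_mean",
    "upstroke_sd",
    "tpl_amp_0.1s",
    "tpl_amp_0.2s",
    "tpl_amp_0.3s",
    "tpl_amp_0.4s",
)

TEMPLATE_SAMPLE_TIMES_S = (0.1, 0.2, 0.3, 0.4)


@dataclass
class PipelineConfig:
    """Beat-pipeline knobs used when analyzing a window."""

    band_hz: tuple[float, float] = (5.0, 25.0)
    rms_window_s: float = 0.1
    min_rr_s: float = 0.4
    prominence_frac: float = 0.3
    segment_window_s: tuple[float, float] = (-0.1, 0.5)
    normalize_first: bool = True
    sqi_cv_scale: float = 0.5
    sqi_threshold: float = SQI_THRESHOLD


@dataclass
class BeatAnalysis:
    enhanced: np.ndarray
    beats_s: np.ndarray
    rr_s: np.ndarray | None
    hr_bpm: float | None
    segments: list
    template: bp.BeatTemplate | None


@dataclass
class SampleWindow:
    """One 45 s pre-measurement analysis window."""

    window_id: int
    fs_hz: float
    samples: np.ndarray
    t0_s: float
    record: BPRecord | None = None
    analysis: BeatAnalysis | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass
class SQIReport:
    sqi: float
    template_consistency: float
    rr_regularity: float
    amplitude_stability: float
    retained: bool


@dataclass
class FeatureVector:
    window_id: int
    values: dict[str, float] = field(default_factory=dict)
    sqi: float = np.nan

    def to_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


def extract_windows(
    sig: np.ndarray,
    fs_hz: float,
    t0s_s,
    records: list[BPRecord] | None = None,
    duration_s: float = WINDOW_DURATION_S,
) -> tuple[list[SampleWindow], int]:
    """Slice the exact [t0 − 45 s, t0) window for each measurement time.

    t0 values earlier than 45 s into the recording (or beyond its end)
    are skipped; the skipped count is returned. Window ids follow the
    position in the t0 list, so reruns yield identical ids.
    """
    t0s = np.atleast_1d(np.asarray(t0s_s, dtype=float))
    if t0s.size == 0:
        raise ValueError("empty t0 list")
    x = np.asarray(sig, dtype=float)
    n_win = int(round(duration_s * fs_hz))
    windows: list[SampleWindow] = []
    skipped = 0
    for i, t0 in enumerate(t0s):
        i1 = int(round(t0 * fs_hz))
        i0 = i1 - n_win
        if i0 < 0 or i1 > len(x):
            skipped += 1
            continue
        rec = records[i] if records is not None else None
        windows.append(
            SampleWindow(
                window_id=i, fs_hz=fs_hz, samples=x[i0:i1].copy(), t0_s=float(t0),
                record=rec,
            )
        )
    return windows, skipped


def normalize_window(samples: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD standardization of one window."""
    x = np.asarray(samples, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("constant window cannot be normalized")
    return (x - np.mean(x)) / sd


def analyze_window(w: SampleWindow, cfg: PipelineConfig | None = None) -> BeatAnalysis:
    """Run the beat pipeline on one window and cache the artifacts."""
    cfg = cfg or PipelineConfig()
    x = w.samples
    if cfg.normalize_first and np.std(x) > 0:
        x = normalize_window(x)
    enhanced = bp.bandpass_enhance(x, w.fs_hz, cfg.band_hz)
    env = bp.rms_envelope(enhanced, w.fs_hz, cfg.rms_window_s)
    beats = bp.detect_beats(env, cfg.min_rr_s, cfg.prominence_frac)
    rr, hr = (None, None)
    if len(beats) >= 2:
        rr, hr = bp.rr_intervals(beats)
    segments, _ = bp.segment_beats(enhanced, w.fs_hz, beats, cfg.segment_window_s)
    template = None
    if len(segments) >= 2:
        template = bp.build_template(
            segments, w.fs_hz, start_s=cfg.segment_window_s[0]
        )
    analysis = BeatAnalysis(enhanced, beats, rr, hr, segments, template)
    w.analysis = analysis
    return analysis


def _cv(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if m == 0:
        return np.inf
    return float(np.std(x) / abs(m))


def compute_sqi(w: SampleWindow, cfg: PipelineConfig | None = None) -> SQIReport:
    """Signal quality index of one window, in [0, 1].

    Geometric mean of template consistency (mean beat-vs-template
    Pearson correlation, clipped to [0, 1]), RR regularity
    exp(−CV(RR)/c) and amplitude stability exp(−CV(p2p)/c). Fewer than
    three detected beats yields SQI 0 and exclusion.
    """
    cfg = cfg or PipelineConfig()
    a = w.analysis or analyze_window(w, cfg)
    if len(a.beats_s) < 3 or a.template is None or len(a.segments) < 3:
        return SQIReport(0.0, 0.0, 0.0, 0.0, False)
    tpl = a.template.waveform
    tpl_sd = np.std(tpl)
    corrs = []
    p2ps = []
    for seg in a.segments:
        s = seg.samples
        if np.std(s) > 0 and tpl_sd > 0:
            corrs.append(float(np.corrcoef(s, tpl)[0, 1]))
        p2ps.append(float(np.ptp(s)))
    consistency = float(np.clip(np.mean(corrs), 0.0, 1.0)) if corrs else 0.0
    rr_reg = float(np.exp(-_cv(a.rr_s) / cfg.sqi_cv_scale))
    amp_stab = float(np.exp(-_cv(np.asarray(p2ps)) / cfg.sqi_cv_scale))
    sqi = float((max(consistency, 0.0) * rr_reg * amp_stab) ** (1.0 / 3.0))
    return SQIReport(sqi, consistency, rr_reg, amp_stab, sqi >= cfg.sqi_threshold)


def extract_features(
    w: SampleWindow, cfg: PipelineConfig | None = None
) -> FeatureVector:
    """Fixed-length feature vector of one retained window.

    Per-beat RMS, peak-to-peak and maximum upstroke slope (first
    difference × fs, units/s) are computed on the band-passed segments
    and aggregated as mean and SD; template amplitudes are read by
    linear interpolation at 0.1–0.4 s after the beat anchor.
    """
    cfg = cfg or PipelineConfig()
    a = w.analysis or analyze_window(w, cfg)
    if a.template is None:
        raise ValueError("window has no template; cannot extract features")
    if a.hr_bpm is None:
        raise ValueError("window has fewer than 2 beats")
    rms_vals, p2p_vals, slope_vals = [], [], []
    for seg in a.segments:
        s = seg.samples
        rms_vals.append(float(np.sqrt(np.mean(s**2))))
        p2p_vals.append(float(np.ptp(s)))
        slope_vals.append(float(np.max(np.diff(s)) * w.fs_hz))
    values = {
        "hr_bpm": a.hr_bpm,
        "rms_mean": float(np.mean(rms_vals)),
        "rms_sd": float(np.std(rms_vals)),
        "p2p_mean": float(np.mean(p2p_vals)),
        "p2p_sd": float(np.std(p2p_vals)),
        "upstroke_mean": float(np.mean(slope_vals)),
        "upstroke_sd": float(np.std(slope_vals)),
    }
    tpl = a.template
    for ts in TEMPLATE_SAMPLE_TIMES_S:
        values[f"tpl_amp_{ts}s"] = float(np.interp(ts, tpl.time_s, tpl.waveform))
    sqi = compute_sqi(w, cfg).sqi
    return FeatureVector(window_id=w.window_id, values=values, sqi=sqi)


def screen_and_featurize(
    windows: list[SampleWindow], cfg: PipelineConfig | None = None
) -> tuple[list[FeatureVector], list[SQIReport], int]:
    """SQI-screen a window list and featurize the retained ones.

    Returns (features of retained windows, all SQI reports, excluded count).
    """
    cfg = cfg or PipelineConfig()
    feats: list[FeatureVector] = []
    reports: list[SQIReport] = []
    excluded = 0
    for w in windows:
        analyze_window(w, cfg)
        rep = compute_sqi(w, cfg)
        reports.append(rep)
        if rep.retained:
            feats.append(extract_features(w, cfg))
        else:
            excluded += 1
    return feats, reports, excluded
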