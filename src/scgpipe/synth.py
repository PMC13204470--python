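"""Synthetic seismocardiogram (SCG) generation with ground-truth annotations.

Chest-wall force waveforms are synthesized as trains of single-beat
complexes, each a superposition of six Gabor wavelets (Gaussian-windowed
cosines) — one per fiducial event of the cardiac cycle: Mid-Cycle (MC),
Isovolumetric Moment (IM), Aortic valve Opening (AO), Isovolumetric
Contraction (IC), Aortic valve Closure (AC) and Mitral valve Opening (MO).
The Gabor model keeps every beat band-limited to the 1–25 Hz range where
SCG energy lives while making each fiducial's latency and amplitude exact,
machine-readable ground truth for the downstream detection stages.

Sessions emulate four activity states (breath-hold, rest, office work,
walking), respiration amplitude modulation, RR jitter, low-frequency
office artifacts (0.5–2 Hz), walking step transients, and cuff blood
pressure measurement events with planted, learnable feature effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FIDUCIAL_ORDER = ("MC", "IM", "AO", "IC", "AC", "MO")

ACTIVITY_STATES = ("breath_hold", "rest", "office", "walking")


@dataclass(frozen=True)
class GaborWavelet:
    """One fiducial event: a Gaussian-windowed cosine burst.

    latency_s   envelope peak time from beat onset (s)
    amplitude_n signed peak force (N); the cosine phase is locked so the
                trace equals ``amplitude_n`` exactly at ``latency_s``
    width_s     Gaussian envelope SD (s)
    freq_hz     carrier frequency (Hz), constrained to 1–25 Hz
    """

    latency_s: float
    amplitude_n: float
    width_s: float
    freq_hz: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError(f"wavelet width must be > 0, got {self.width_s}")
        if not (1.0 <= self.freq_hz <= 25.0):
            raise ValueError(
                f"carrier frequency must lie in [1, 25] Hz, got {self.freq_hz}"
            )


@dataclass(frozen=True)
class FiducialSpec:
    """Per-event wavelet parameters for one beat complex.

    Latencies must be strictly increasing in the physiological order
    MC < IM < AO < IC < AC < MO.
    """

    events: dict[str, GaborWavelet]

    def __post_init__(self) -> None:
        missing = [e for e in FIDUCIAL_ORDER if e not in self.events]
        if missing:
            raise ValueError(f"missing fiducial events: {missing}")
        lat = [self.events[e].latency_s for e in FIDUCIAL_ORDER]
        if not all(a < b for a, b in zip(lat, lat[1:])):
            raise ValueError(
                f"fiducial latencies must be strictly increasing "
                f"in order {FIDUCIAL_ORDER}, got {lat}"
            )

    def latency(self, event: str) -> float:
        return self.events[event].latency_s

    def scaled(self, amplitude_factor: float) -> "FiducialSpec":
        """Return a copy with every event amplitude multiplied by a factor."""
        return FiducialSpec(
            {
                name: replace(w, amplitude_n=w.amplitude_n * amplitude_factor)
                for name, w in self.events.items()
            }
        )

    def scaled_event(self, event: str, amplitude_factor: float) -> "FiducialSpec":
        """Return a copy with one event's amplitude multiplied by a factor."""
        events = dict(self.events)
        w = events[event]
        events[event] = replace(w, amplitude_n=w.amplitude_n * amplitude_factor)
        return FiducialSpec(events)


def default_fiducial_spec() -> FiducialSpec:
    """Canonical beat morphology: MC→MO over 0.06–0.41 s, AO dominant.

    AO is the largest positive systolic peak; IM and IC flank it as
    troughs; AC/MO form the smaller diastolic complex. Carrier
    frequencies (8–13 Hz) and widths (16–20 ms) put well over 80% of a
    session's energy inside the 1–20 Hz SCG band while keeping carrier
    side-lobes below 6% of the main lobe, so peak/trough detection on
    the template stays unambiguous.
    """
    return FiducialSpec(
        {
            "MC": GaborWavelet(0.06, +0.035, 0.016, 10.0),
            "IM": GaborWavelet(0.12, -0.060, 0.016, 12.0),
            "AO": GaborWavelet(0.17, +0.130, 0.016, 13.0),
            "IC": GaborWavelet(0.22, -0.070, 0.016, 12.0),
            "AC": GaborWavelet(0.34, +0.070, 0.018, 9.0),
            "MO": GaborWavelet(0.41, -0.050, 0.020, 8.0),
        }
    )


@dataclass(frozen=True)
class SessionProtocol:
    """Recording-session recipe for one activity state.

    Heart-rate defaults follow the two cycle lengths observed on the
    bench: ≈1 s per beat while breath-holding (60 bpm) and ≈0.8 s at
    rest (75 bpm). Respiration modulates beat amplitudes multiplicatively;
    breath-hold forces the modulation depth to zero.
    """

    state: str = "rest"
    duration_s: float = 60.0
    heart_rate_bpm: float = 75.0
    rr_jitter_sd_s: float = 0.02
    respiration_hz: float = 0.25
    respiration_depth: float = 0.2
    office_artifact_amp_n: float = 0.05
    walking_step_rate_hz: float = 2.0
    walking_transient_amp_n: float = 0.3
    mains_amp_v: float = 0.0
    fs_hz: float = 1000.0
    fiducials: FiducialSpec = field(default_factory=default_fiducial_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in ACTIVITY_STATES:
            raise ValueError(f"unknown activity state {self.state!r}")
        if self.duration_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("duration and heart rate must be positive")
        if not (0.0 <= self.respiration_depth < 1.0):
            raise ValueError("respiration depth must lie in [0, 1)")
        if self.state == "breath_hold" and self.respiration_depth != 0.0:
            raise ValueError("breath_hold requires respiration depth 0")


def breath_hold_protocol(**kw) -> SessionProtocol:
    """60 bpm, no respiration modulation, no jitter unless overridden."""
    defaults = dict(
        state="breath_hold",
        heart_rate_bpm=60.0,
        respiration_depth=0.0,
        rr_jitter_sd_s=0.0,
    )
    defaults.update(kw)
    return SessionProtocol(**defaults)


def rest_protocol(**kw) -> SessionProtocol:
    defaults = dict(state="rest", heart_rate_bpm=75.0)
    defaults.update(kw)
    return SessionProtocol(**defaults)


@dataclass
class ForceWaveform:
    """Uniformly sampled chest-wall force trace with ground truth.

    onsets_s            beat-onset times (s)
    ao_times_s          onset + AO latency per beat (dominant-event truth)
    amplitude_scales    multiplicative per-beat amplitude factors applied
                        on top of the fiducial spec (respiration etc.)
    artifact_intervals  (start_s, end_s, kind) segments of added artifact
    """

    fs_hz: float
    samples: np.ndarray
    onsets_s: np.ndarray
    ao_times_s: np.ndarray
    amplitude_scales: np.ndarray
    artifact_intervals: list[tuple[float, float, str]]
    protocol: SessionProtocol | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs_hz

    def copy(self) -> "ForceWaveform":
        return ForceWaveform(
            fs_hz=self.fs_hz,
            samples=self.samples.copy(),
            onsets_s=self.onsets_s.copy(),
            ao_times_s=self.ao_times_s.copy(),
            amplitude_scales=self.amplitude_scales.copy(),
            artifact_intervals=list(self.artifact_intervals),
            protocol=self.protocol,
        )


@dataclass(frozen=True)
class BPRecord:
    """One cuff blood-pressure measurement event.

    t0_s is the measurement instant; the preceding 45 s of signal form
    the associated analysis window, so t0_s must be at least 45 s.
    """

    t0_s: float
    sbp_mmhg: float
    dbp_mmhg: float
    sbp_class: int
    dbp_class: int

    def __post_init__(self) -> None:
        from .bp_classifier import discretize_bp

        if self.t0_s < 45.0:
            raise ValueError("t0 must allow a full 45 s window before it")
        sc, dc = discretize_bp(self.sbp_mmhg, self.dbp_mmhg)
        if (sc, dc) != (self.sbp_class, self.dbp_class):
            raise ValueError(
                f"class labels ({self.sbp_class}, {self.dbp_class}) inconsistent "
                f"with values ({self.sbp_mmhg}, {self.dbp_mmhg}) → ({sc}, {dc})"
            )


def generate_beat(spec: FiducialSpec, fs_hz: float) -> np.ndarray:
    """Synthesize one beat as the sum of six Gabor wavelets.

    Each wavelet is ``A·exp(−(t−L)²/2w²)·cos(2πf(t−L))`` so its envelope
    (and, for an isolated event, the trace itself) peaks at the latency
    with value A. The trace spans max latency + 3 × max width.
    """
    if fs_hz < 200.0:
        raise ValueError(f"sampling rate must be ≥ 200 Hz, got {fs_hz}")
    wavelets = [spec.events[e] for e in FIDUCIAL_ORDER]
    t_end = max(w.latency_s for w in wavelets) + 3.0 * max(w.width_s for w in wavelets)
    n = int(round(t_end * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    beat = np.zeros(n)
    for w in wavelets:
        dt = t - w.latency_s
        beat += (
            w.amplitude_n
            * np.exp(-(dt**2) / (2.0 * w.width_s**2))
            * np.cos(2.0 * np.pi * w.freq_hz * dt)
        )
    return beat


def generate_session(protocol: SessionProtocol) -> ForceWaveform:
    """Place beats along a session according to the protocol.

    Beat onsets follow RR = 60/HR + Gaussian jitter (clipped at ±3 SD,
    RR floored at 0.3 s). Respiration multiplies beat amplitudes by
    (1 + depth·sin(2π·f_resp·t_onset)). Identical protocols (including
    seed) produce bit-identical waveforms.
    """
    fs = protocol.fs_hz
    rr_base = 60.0 / protocol.heart_rate_bpm
    if protocol.duration_s < rr_base:
        raise ValueError(
            f"duration {protocol.duration_s} s shorter than one RR ({rr_base} s)"
        )
    rng = np.random.default_rng(np.uint32(protocol.seed))
    n = int(round(protocol.duration_s * fs))
    samples = np.zeros(n)

    onsets: list[float] = []
    scales: list[float] = []
    t = 0.0
    while t < protocol.duration_s:
        onsets.append(t)
        jitter = (
            float(
                np.clip(
                    rng.normal(0.0, protocol.rr_jitter_sd_s),
                    -3.0 * protocol.rr_jitter_sd_s,
                    3.0 * protocol.rr_jitter_sd_s,
                )
            )
            if protocol.rr_jitter_sd_s > 0
            else 0.0
        )
        t += max(0.3, rr_base + jitter)

    beat = generate_beat(protocol.fiducials, fs)
    for onset in onsets:
        scale = 1.0 + protocol.respiration_depth * np.sin(
            2.0 * np.pi * protocol.respiration_hz * onset
        )
        i0 = int(round(onset * fs))
        i1 = min(i0 + len(beat), n)
        samples[i0:i1] += scale * beat[: i1 - i0]
        scales.append(scale)

    onsets_arr = np.asarray(onsets)
    ao_lat = protocol.fiducials.latency("AO")
    return ForceWaveform(
        fs_hz=fs,
        samples=samples,
        onsets_s=onsets_arr,
        ao_times_s=onsets_arr + ao_lat,
        amplitude_scales=np.asarray(scales),
        artifact_intervals=[],
        protocol=protocol,
    )


def add_activity_artifacts(
    waveform: ForceWaveform, protocol: SessionProtocol
) -> ForceWaveform:
    """Add activity-state artifacts; identity for rest / breath-hold.

    Office work contributes band-limited noise synthesized directly in the
    0.5–2 Hz Fourier band (postural micro-movements), so its energy is
    confined to that band by construction. Walking contributes a periodic
    train of Gaussian step transients at the step rate.
    """
    if protocol.state in ("rest", "breath_hold"):
        return waveform
    out = waveform.copy()
    n = len(out.samples)
    fs = out.fs_hz
    rng = np.random.default_rng([np.uint32(protocol.seed), 1])

    if protocol.state == "office":
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        spectrum = np.zeros(len(freqs), dtype=complex)
        band = (freqs >= 0.5) & (freqs <= 2.0)
        k = int(band.sum())
        spectrum[band] = rng.normal(size=k) + 1j * rng.normal(size=k)
        noise = np.fft.irfft(spectrum, n=n)
        rms = np.sqrt(np.mean(noise**2))
        if rms > 0:
            noise *= protocol.office_artifact_amp_n / rms
        out.samples = out.samples + noise
        out.artifact_intervals.append((0.0, out.duration_s, "office"))
    elif protocol.state == "walking":
        t = out.time_s
        step_period = 1.0 / protocol.walking_step_rate_hz
        component = np.zeros(n)
        sigma = 0.08  # step-impact spread (s); fundamental dominates harmonics
        t_step = 0.0
        while t_step < out.duration_s:
            component += np.exp(-((t - t_step) ** 2) / (2.0 * sigma**2))
            t_step += step_period
        component -= component.mean()
        component *= protocol.walking_transient_amp_n
        out.samples = out.samples + component
        out.artifact_intervals.append((0.0, out.duration_s, "walking"))
    return out


@dataclass(frozen=True)
class BPEffectMapping:
    """Planted class-conditional effects linking sessions to BP labels.

    SBP class scales overall beat amplitude (AO dominant); DBP class
    scales heart rate via uniform time compression. Class-conditional
    SBP/DBP values are drawn from truncated normals confined to the
    clinical bins (SBP: <120 / 120–135 / >135 mmHg; DBP: <80 / 80–85 /
    >85 mmHg). Zero-effect mappings (all factors 1) make the planted
    features uninformative — the null case.
    """

    amplitude_factors: tuple[float, float, float] = (0.75, 1.0, 1.25)
    hr_factors: tuple[float, float, float] = (0.85, 1.0, 1.15)
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    sbp_params: tuple[tuple[float, float, float, float], ...] = (
        (110.0, 6.0, 90.0, 119.9),
        (127.5, 4.0, 120.0, 135.0),
        (143.0, 6.0, 135.1, 170.0),
    )
    dbp_params: tuple[tuple[float, float, float, float], ...] = (
        (72.0, 4.0, 55.0, 79.9),
        (82.5, 1.4, 80.0, 85.0),
        (91.0, 4.0, 85.1, 110.0),
    )


def null_effect_mapping() -> BPEffectMapping:
    return BPEffectMapping(
        amplitude_factors=(1.0, 1.0, 1.0), hr_factors=(1.0, 1.0, 1.0)
    )


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform()
    return float(stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def _time_rescale(w: ForceWaveform, factor: float) -> None:
    """Compress (factor > 1) or stretch the session in time, in place.

    Multiplies the instantaneous heart rate by ``factor``; annotations
    are rescaled consistently. Linear interpolation is adequate: session
    content lives far below Nyquist.
    """
    if factor == 1.0:
        return
    fs = w.fs_hz
    old_t = np.arange(len(w.samples)) / fs
    new_n = int(round(len(w.samples) / factor))
    new_t = np.arange(new_n) / fs
    w.samples = np.interp(new_t * factor, old_t, w.samples)
    w.onsets_s = w.onsets_s / factor
    w.ao_times_s = w.ao_times_s / factor
    w.artifact_intervals = [
        (a / factor, b / factor, kind) for a, b, kind in w.artifact_intervals
    ]


def synthesize_bp_dataset(
    sessions: list[ForceWaveform],
    mapping: BPEffectMapping | None = None,
    seed: int = 0,
) -> list[BPRecord]:
    """Assign BP measurement events to sessions, planting learnable effects.

    For each session a SBP class and a DBP class are drawn; SBP/DBP
    values come from the class-conditional truncated normals. The
    session is then modified **in place** so the label→feature relation
    is real, monotone and documented: the SBP class scales the AO
    wavelet amplitude (a relative morphology change that survives
    per-window normalization) and the DBP class scales the mean heart
    rate. Sessions carrying their protocol are regenerated from it with
    the planted parameters; protocol-less sessions fall back to a
    global amplitude scale plus uniform time compression. t0 is placed
    at the session end.
    """
    from .bp_classifier import discretize_bp

    if not sessions:
        raise ValueError("empty session list")
    mapping = mapping or BPEffectMapping()
    records: list[BPRecord] = []
    for i, sess in enumerate(sessions):
        rng = np.random.default_rng([np.uint32(seed), np.uint32(i)])
        sbp_class = int(rng.choice(3, p=mapping.class_probs))
        dbp_class = int(rng.choice(3, p=mapping.class_probs))
        sbp = _truncnorm(rng, *mapping.sbp_params[sbp_class])
        dbp = _truncnorm(rng, *mapping.dbp_params[dbp_class])
        amp = mapping.amplitude_factors[sbp_class]
        hrf = mapping.hr_factors[dbp_class]
        if sess.protocol is not None:
            proto = replace(
                sess.protocol,
                fiducials=sess.protocol.fiducials.scaled_event("AO", amp),
                heart_rate_bpm=sess.protocol.heart_rate_bpm * hrf,
            )
            planted = generate_session(proto)
            sess.samples = planted.samples
            sess.onsets_s = planted.onsets_s
            sess.ao_times_s = planted.ao_times_s
            sess.amplitude_scales = planted.amplitude_scales
            sess.protocol = proto
        else:
            sess.samples = sess.samples * amp
            sess.amplitude_scales = sess.amplitude_scales * amp
            _time_rescale(sess, hrf)
        t0 = sess.duration_s
        if t0 < 45.0:
            raise ValueError(
                f"session {i} is {t0:.1f} s after rescaling; ≥ 45 s needed"
            )
        sc, dc = discretize_bp(sbp, dbp)
        records.append(BPRecord(t0, sbp, dbp, sc, dc))
    return records


def generate_bp_dataset(
    n_sessions: int,
    mapping: BPEffectMapping | None = None,
    base_protocol: SessionProtocol | None = None,
    seed: int = 0,
) -> tuple[list[ForceWaveform], list[BPRecord]]:
    """Build n base sessions and plant BP effects; the one-stop generator.

    Base sessions are 55 s resting recordings; after the largest default
    heart-rate compression (×1.15) they remain ≥ 47 s, long enough for a
    45 s pre-measurement window.
    """
    base = base_protocol or rest_protocol(duration_s=55.0)
    sessions = [
        generate_session(replace(base, seed=int(np.random.default_rng(
            [np.uint32(seed), np.uint32(i), 7]).integers(2**31))))
        for i in range(n_sessions)
    ]
    records = synthesize_bp_dataset(sessions, mapping, seed=seed)
    return sessions, records
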