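"""Digital twin of the triboelectric force sensor and analog front end.

Force in, digitized voltage out. The chain mirrors the acquisition
hardware stage by stage:

  sensor static response (piecewise sensitivity: 3.76 V/N below 0.2 N,
  0.10 V/N above 0.6 N, linearly blended slope across the knee)
    → asymmetric first-order dynamics (10–90% rise 0.02 s, fall 0.06 s)
    → transimpedance-stage pole (10 MΩ ∥ 20 pF → 796 Hz)
    → 3rd-order Butterworth low-pass, −3 dB at 33.9 Hz
    → gain → 50 Hz notch → first-order high-pass at 0.8 Hz
    → mid-scale level shift → 12-bit ADC at 1000 Hz (LSB 0.732 mV).

The sensor is modeled as a voltage source feeding the transimpedance
stage's single pole — a phenomenological stand-in for the contact-
separation charge cycle that avoids an unknowable electrostatic model.
All filters are causal discrete-time designs (the real front end is
causal); offline analysis filtering lives in :mod:`scgpipe.beat_pipeline`
and is zero-phase by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal


@dataclass(frozen=True)
class SensorParams:
    """Triboelectric sensor calibration.

    s1_v_per_n  low-range sensitivity on 0–0.2 N (V/N)
    s2_v_per_n  high-range sensitivity on 0.6–0.8 N (V/N)
    knee_n      (start, end) of the sensitivity transition (N)
    t_rise_s    10–90% step response time (s)
    t_fall_s    90–10% step recovery time (s)
    band_hz     nominally flat response band (Hz)
    """

    s1_v_per_n: float = 3.76
    s2_v_per_n: float = 0.10
    knee_n: tuple[float, float] = (0.2, 0.6)
    t_rise_s: float = 0.02
    t_fall_s: float = 0.06
    band_hz: tuple[float, float] = (0.5, 25.0)

    def __post_init__(self) -> None:
        if not (self.s1_v_per_n > self.s2_v_per_n > 0):
            raise ValueError("require S1 > S2 > 0")
        if not (self.t_fall_s > self.t_rise_s > 0):
            raise ValueError("require fall time > rise time > 0")


@dataclass(frozen=True)
class AnalogChainParams:
    """Front-end circuit parameters.

    The ADC full scale defaults to 3.0 V: a 12-bit converter quoted at a
    0.732 mV step implies 0.732 mV × 4096 = 3.0 V (the 3.3 V logic rail
    would give 0.806 mV). The gain is chosen so a 0.2 N static beat peak
    lands near 60% of full scale; the notch quality factor 10 is narrow
    enough to spare the 1–20 Hz SCG band.
    """

    rf_ohm: float = 10e6
    cf_f: float = 20e-12
    lp_order: int = 3
    lp_cutoff_hz: float = 33.9
    gain: float = 0.4
    notch_hz: float = 50.0
    notch_q: float = 10.0
    hp_corner_hz: float = 0.8
    adc_bits: int = 12
    adc_full_scale_v: float = 3.0
    adc_fs_hz: float = 1000.0
    mid_offset_v: float = 1.5

    def __post_init__(self) -> None:
        if self.hp_corner_hz >= self.lp_cutoff_hz:
            raise ValueError("high-pass corner must lie below low-pass cutoff")
        if self.adc_bits < 1 or self.adc_full_scale_v <= 0:
            raise ValueError("invalid ADC configuration")
        if not (self.hp_corner_hz < self.notch_hz < self.adc_fs_hz / 2):
            raise ValueError("notch must lie between high-pass corner and Nyquist")

    @property
    def tia_pole_hz(self) -> float:
        return 1.0 / (2.0 * np.pi * self.rf_ohm * self.cf_f)

    @property
    def lsb_v(self) -> float:
        return self.adc_full_scale_v / 2**self.adc_bits


@dataclass
class DigitizedSignal:
    """Quantized front-end output at the ADC rate."""

    fs_hz: float
    codes: np.ndarray
    lsb_v: float
    metadata: dict = field(default_factory=dict)

    @property
    def voltage_v(self) -> np.ndarray:
        return self.codes * self.lsb_v

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.codes)) / self.fs_hz


def static_response(force_n, params: SensorParams | None = None):
    """Quasi-static force → voltage map.

    Slope S1 on [0, knee start], S2 beyond the knee end, with the slope
    interpolated linearly across the knee (so the voltage is quadratic
    there and the map is C¹, continuous and monotone).
    """
    p = params or SensorParams()
    f = np.asarray(force_n, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be nonnegative")
    k0, k1 = p.knee_n
    s1, s2 = p.s1_v_per_n, p.s2_v_per_n
    v_k0 = s1 * k0
    v_k1 = v_k0 + 0.5 * (s1 + s2) * (k1 - k0)
    out = np.where(
        f <= k0,
        s1 * f,
        np.where(
            f >= k1,
            v_k1 + s2 * (f - k1),
            v_k0 + s1 * (f - k0) + 0.5 * (s2 - s1) * (f - k0) ** 2 / (k1 - k0),
        ),
    )
    return out if out.ndim else float(out)


@njit(cache=True)
def _asym_first_order(target, alpha_rise, alpha_fall):  # pragma: no cover
    out = np.empty_like(target)
    y = target[0]
    out[0] = y
    for i in range(1, len(target)):
        a = alpha_rise if target[i] > y else alpha_fall
        y += a * (target[i] - y)
        out[i] = y
    return out


def apply_sensor_dynamics(
    force_n: np.ndarray, fs_hz: float, params: SensorParams | None = None
) -> np.ndarray:
    """Static response followed by asymmetric first-order smoothing.

    Rise and fall time constants are set from the calibrated 10–90%
    step times via τ = t / ln 9, so a simulated step reproduces the
    bench rise/recovery times to within one sample. The smoothing acts
    on the voltage after the static map (output tracks toward the static
    target, faster when rising than falling).
    """
    if fs_hz < 200.0:
        raise ValueError(f"sampling rate must be ≥ 200 Hz, got {fs_hz}")
    p = params or SensorParams()
    target = np.asarray(static_response(force_n, p), dtype=float)
    ln9 = np.log(9.0)
    tau_r = p.t_rise_s / ln9
    tau_f = p.t_fall_s / ln9
    dt = 1.0 / fs_hz
    a_r = 1.0 - np.exp(-dt / tau_r)
    a_f = 1.0 - np.exp(-dt / tau_f)
    return _asym_first_order(target, a_r, a_f)


def _sos_for_stage(stage: str, fs_hz: float, p: AnalogChainParams) -> np.ndarray | None:
    nyq = fs_hz / 2.0
    if stage == "tia":
        # Pole above (or too near) Nyquist: in-band effect < 0.01 dB, skip.
        if p.tia_pole_hz >= 0.45 * fs_hz:
            return None
        return signal.butter(1, p.tia_pole_hz, "lowpass", fs=fs_hz, output="sos")
    if stage == "lowpass":
        if p.lp_cutoff_hz >= nyq:
            raise ValueError("low-pass cutoff must lie below Nyquist")
        return signal.butter(p.lp_order, p.lp_cutoff_hz, "lowpass", fs=fs_hz, output="sos")
    if stage == "notch":
        b, a = signal.iirnotch(p.notch_hz, p.notch_q, fs=fs_hz)
        return signal.tf2sos(b, a)
    if stage == "highpass":
        return signal.butter(1, p.hp_corner_hz, "highpass", fs=fs_hz, output="sos")
    raise ValueError(f"unknown stage {stage!r}")


def _sosfilt_settled(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Causal filtering with the filter pre-settled to the first sample.

    Initial conditions are set to the DC steady state for x[0], so a
    recording that starts at its operating point (a worn, powered-on
    device) shows no artificial power-up transient.
    """
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def apply_analog_chain(
    voltage_v: np.ndarray,
    fs_hz: float,
    params: AnalogChainParams | None = None,
    mains_amp_v: float = 0.0,
) -> np.ndarray:
    """Run the sensor voltage through the conditioning chain.

    Order: additive 50 Hz mains pickup (the single-electrode structure
    is susceptible to it) → transimpedance pole → 3rd-order Butterworth
    low-pass → gain → notch → first-order high-pass → mid-scale offset.
    Returns the pre-ADC analog signal at the input rate.
    """
    p = params or AnalogChainParams()
    v = np.asarray(voltage_v, dtype=float)
    if mains_amp_v != 0.0:
        t = np.arange(len(v)) / fs_hz
        v = v + mains_amp_v * np.sin(2.0 * np.pi * p.notch_hz * t)
    for stage in ("tia", "lowpass"):
        sos = _sos_for_stage(stage, fs_hz, p)
        if sos is not None:
            v = _sosfilt_settled(sos, v)
    v = v * p.gain
    for stage in ("notch", "highpass"):
        v = _sosfilt_settled(_sos_for_stage(stage, fs_hz, p), v)
    return v + p.mid_offset_v


def digitize(
    voltage_v: np.ndarray,
    fs_hz: float,
    params: AnalogChainParams | None = None,
) -> DigitizedSignal:
    """Anti-aliased resampling to the ADC rate, clipping and quantization.

    The analog value is clipped to the representable range
    [0, (2^bits − 1)·LSB] and rounded to the nearest code, so the
    quantization error never exceeds LSB/2. Clipped-sample counts are
    recorded in the metadata rather than raised.
    """
    p = params or AnalogChainParams()
    v = np.asarray(voltage_v, dtype=float)
    if fs_hz < p.adc_fs_hz:
        raise ValueError("analog series must be sampled at ≥ the ADC rate")
    if fs_hz != p.adc_fs_hz:
        from fractions import Fraction

        frac = Fraction(p.adc_fs_hz / fs_hz).limit_denominator(10_000)
        v = signal.resample_poly(v, frac.numerator, frac.denominator)
    lsb = p.lsb_v
    n_codes = 2**p.adc_bits
    v_max = (n_codes - 1) * lsb
    n_clipped = int(np.sum((v < 0) | (v > v_max)))
    clipped = np.clip(v, 0.0, v_max)
    codes = np.round(clipped / lsb).astype(np.int32)
    return DigitizedSignal(
        fs_hz=p.adc_fs_hz,
        codes=codes,
        lsb_v=lsb,
        metadata={"params": p, "n_clipped": n_clipped},
    )


def simulate_session(
    force_n: np.ndarray,
    fs_hz: float,
    sensor: SensorParams | None = None,
    chain: AnalogChainParams | None = None,
    mains_amp_v: float = 0.0,
    preload_n: float = 0.15,
) -> DigitizedSignal:
    """Full forward model: force trace → digitized front-end output.

    The chest strap preloads the sensor, so the signed vibration trace
    rides on a static contact force ``preload_n`` (default 0.15 N, the
    middle of the high-sensitivity range); excursions below zero force
    — loss of contact — saturate at zero.
    """
    force = np.maximum(np.asarray(force_n, dtype=float) + preload_n, 0.0)
    v = apply_sensor_dynamics(force, fs_hz, sensor)
    v = apply_analog_chain(v, fs_hz, chain, mains_amp_v=mains_amp_v)
    return digitize(v, fs_hz, chain)


def _sine_amplitude(y: np.ndarray, fs_hz: float, f_hz: float) -> float:
    """Steady-state amplitude at f via a single-bin DFT over whole periods."""
    n_keep = int(np.floor(len(y) / 2 / fs_hz * f_hz) / f_hz * fs_hz)
    if n_keep < 8:
        n_keep = len(y) // 2
    seg = y[-n_keep:]
    t = np.arange(len(seg)) / fs_hz
    c = np.mean(seg * np.exp(-2j * np.pi * f_hz * t))
    return 2.0 * float(np.abs(c))


def frequency_response(
    stage: str,
    freqs_hz,
    params: AnalogChainParams | None = None,
    fs_hz: float = 4000.0,
) -> np.ndarray:
    """Swept-sine magnitude response (dB) of one stage or the full chain.

    Each probe frequency is measured in steady state (≥ 6 periods after
    a settling interval), normalized to unity (0 dB) at the stage's
    nominal passband gain. ``stage`` ∈ {"tia", "lowpass", "notch",
    "highpass", "chain"}.
    """
    p = params or AnalogChainParams()
    freqs = np.asarray(freqs_hz, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    if np.any(freqs >= fs_hz / 2):
        raise ValueError("probe frequencies must lie below Nyquist")

    if stage == "chain":
        soses = [
            _sos_for_stage(s, fs_hz, p)
            for s in ("tia", "lowpass", "notch", "highpass")
        ]
        soses = [s for s in soses if s is not None]
        gain = p.gain
    else:
        sos = _sos_for_stage(stage, fs_hz, p)
        soses = [sos] if sos is not None else []
        gain = 1.0

    mags = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        duration = max(2.0, 8.0 / f)
        t = np.arange(int(round(duration * fs_hz))) / fs_hz
        x = np.sin(2.0 * np.pi * f * t)
        y = x
        for sos in soses:
            y = signal.sosfilt(sos, y)
        y = y * gain
        mags[i] = _sine_amplitude(y, fs_hz, f) / gain
    return 20.0 * np.log10(np.maximum(mags, 1e-12))


def measure_cutoff(
    stage: str,
    f_lo: float,
    f_hi: float,
    params: AnalogChainParams | None = None,
    fs_hz: float = 4000.0,
    n_points: int = 60,
    kind: str = "lowpass",
) -> float:
    """Locate the −3 dB crossing of a stage by log-spaced sweep.

    ``kind`` selects the crossing direction: "lowpass" finds the highest
    frequency still within 3 dB of the passband, "highpass" the lowest.
    The crossing is refined by linear interpolation in (log f, dB).
    """
    freqs = np.geomspace(f_lo, f_hi, n_points)
    mags = frequency_response(stage, freqs, params, fs_hz=fs_hz)
    ref = mags[0] if kind == "lowpass" else mags[-1]
    rel = mags - ref
    target = -3.0103  # 20·log10(1/sqrt 2)
    if kind == "lowpass":
        idx = np.nonzero(rel <= target)[0]
        if idx.size == 0 or idx[0] == 0:
            raise ValueError("no −3 dB crossing inside the sweep range")
        i = idx[0]
        j = i - 1
    else:
        idx = np.nonzero(rel <= target)[0]
        if idx.size == 0 or idx[-1] == len(freqs) - 1:
            raise ValueError("no −3 dB crossing inside the sweep range")
        j = idx[-1]
        i = j + 1
    x0, x1 = rel[j], rel[i]
    y0, y1 = np.log(freqs[j]), np.log(freqs[i])
    lf = y0 + (target - x0) * (y1 - y0) / (x1 - x0) if x1 != x0 else y0
    return float(np.exp(lf))


def measure_notch_center(
    params: AnalogChainParams | None = None,
    f_lo: float = 30.0,
    f_hi: float = 70.0,
    step_hz: float = 0.1,
    fs_hz: float = 4000.0,
) -> float:
    """Argmin of the notch stage's swept magnitude response."""
    freqs = np.arange(f_lo, f_hi + step_hz / 2, step_hz)
    mags = frequency_response("notch", freqs, params, fs_hz=fs_hz)
    return float(freqs[int(np.argmin(mags))])


def measure_step_times(
    params: SensorParams | None = None,
    step_force_n: float = 0.1,
    fs_hz: float = 4000.0,
) -> tuple[float, float]:
    """Simulated 10–90% rise and 90–10% fall times of the sensor model.

    Applies a 0 → step → 0 force profile through the dynamic model and
    interpolates the threshold crossings for sub-sample accuracy.
    """
    p = params or SensorParams()
    hold = int(round(10.0 * p.t_fall_s * fs_hz))
    force = np.concatenate(
        [np.zeros(hold), np.full(hold, step_force_n), np.zeros(hold)]
    )
    out = apply_sensor_dynamics(force, fs_hz, p)
    v_ss = static_response(step_force_n, p)

    def crossing(seg: np.ndarray, level: float, rising: bool) -> float:
        if rising:
            i = int(np.argmax(seg >= level))
        else:
            i = int(np.argmax(seg <= level))
        if i == 0:
            return 0.0
        y0, y1 = seg[i - 1], seg[i]
        frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
        return (i - 1 + frac) / fs_hz

    rise_seg = out[hold : 2 * hold]
    t10 = crossing(rise_seg, 0.1 * v_ss, rising=True)
    t90 = crossing(rise_seg, 0.9 * v_ss, rising=True)
    fall_seg = out[2 * hold :]
    t90f = crossing(fall_seg, 0.9 * v_ss, rising=False)
    t10f = crossing(fall_seg, 0.1 * v_ss, rising=False)
    return t90 - t10, t10f - t90f
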