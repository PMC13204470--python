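"""CSV/JSON/YAML readers and writers for all pipeline artifacts.

Time series go to plain CSV (`time_s,<value column>`) with JSON
annotation sidecars; everything round-trips losslessly through its
reader (floats are written with full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward_model import DigitizedSignal
from .synth import BPRecord, ForceWaveform


class SignalFormatError(ValueError):
    pass


def write_signal_csv(path, time_s: np.ndarray, values: np.ndarray, column: str) -> None:
    df = pd.DataFrame({"time_s": time_s, column: values})
    df.to_csv(path, index=False, float_format="%.12g")


def read_signal_csv(path) -> tuple[np.ndarray, np.ndarray, str, float]:
    """Read a uniform time series; returns (time, values, column, fs).

    Validates strictly monotone time at a uniform step (relative
    tolerance 1e-6); the error message names the first offending row
    (1-based data rows, as in the file after the header).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns or len(df.columns) < 2:
        raise SignalFormatError(
            f"{path}: expected header 'time_s,<value column>', got {list(df.columns)}"
        )
    column = [c for c in df.columns if c != "time_s"][0]
    t = df["time_s"].to_numpy(dtype=float)
    v = df[column].to_numpy(dtype=float)
    if len(t) < 2:
        return t, v, column, np.nan
    dt = np.diff(t)
    step = dt[0]
    if step <= 0:
        raise SignalFormatError(f"{path}: non-increasing time at row 2")
    bad = np.flatnonzero(np.abs(dt - step) > 1e-6 * abs(step))
    if bad.size:
        raise SignalFormatError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 2} "
            f"(step {dt[bad[0]]:.9g}, expected {step:.9g})"
        )
    return t, v, column, 1.0 / step


def write_waveform(path_prefix, w: ForceWaveform) -> tuple[Path, Path]:
    """Write a force waveform as CSV plus a JSON annotation sidecar."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    write_signal_csv(csv_path, w.time_s, w.samples, "force_N")
    meta = {
        "fs_hz": w.fs_hz,
        "onsets_s": w.onsets_s.tolist(),
        "ao_times_s": w.ao_times_s.tolist(),
        "amplitude_scales": w.amplitude_scales.tolist(),
        "artifact_intervals": [list(iv) for iv in w.artifact_intervals],
    }
    if w.protocol is not None:
        p = w.protocol
        meta["protocol"] = {
            "state": p.state,
            "duration_s": p.duration_s,
            "heart_rate_bpm": p.heart_rate_bpm,
            "rr_jitter_sd_s": p.rr_jitter_sd_s,
            "respiration_hz": p.respiration_hz,
            "respiration_depth": p.respiration_depth,
            "seed": p.seed,
        }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def read_waveform(path_prefix) -> ForceWaveform:
    prefix = Path(path_prefix)
    t, v, column, fs = read_signal_csv(prefix.with_suffix(".csv"))
    if column != "force_N":
        raise SignalFormatError(f"expected force_N column, got {column}")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return ForceWaveform(
        fs_hz=meta["fs_hz"],
        samples=v,
        onsets_s=np.asarray(meta["onsets_s"]),
        ao_times_s=np.asarray(meta["ao_times_s"]),
        amplitude_scales=np.asarray(meta["amplitude_scales"]),
        artifact_intervals=[tuple(iv) for iv in meta["artifact_intervals"]],
    )


def write_digitized(path, sig: DigitizedSignal) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": sig.time_s,
            "voltage_V": sig.voltage_v,
            "code": sig.codes,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_digitized(path, lsb_v: float | None = None) -> DigitizedSignal:
    df = pd.read_csv(path)
    for col in ("time_s", "code"):
        if col not in df.columns:
            raise SignalFormatError(f"{path}: missing column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else np.nan
    codes = df["code"].to_numpy(dtype=np.int32)
    if lsb_v is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = df["voltage_V"].to_numpy(dtype=float)[codes != 0] / codes[codes != 0]
        lsb_v = float(np.median(ratios)) if ratios.size else 0.0
    return DigitizedSignal(fs_hz=fs, codes=codes, lsb_v=lsb_v)


def write_bp_records(path, records: list[BPRecord]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t0_s": [r.t0_s for r in records],
            "sbp_mmHg": [r.sbp_mmhg for r in records],
            "dbp_mmHg": [r.dbp_mmhg for r in records],
            "sbp_class": [r.sbp_class for r in records],
            "dbp_class": [r.dbp_class for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_bp_records(path) -> list[BPRecord]:
    df = pd.read_csv(path)
    return [
        BPRecord(
            t0_s=row.t0_s,
            sbp_mmhg=row.sbp_mmHg,
            dbp_mmhg=row.dbp_mmHg,
            sbp_class=int(row.sbp_class),
            dbp_class=int(row.dbp_class),
        )
        for row in df.itertuples()
    ]


def write_features_csv(path, features) -> Path:
    from .quality_features import FEATURE_NAMES

    path = Path(path)
    rows = []
    for f in features:
        row = {"window_id": f.window_id, "sqi": f.sqi}
        row.update({k: f.values[k] for k in FEATURE_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path
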