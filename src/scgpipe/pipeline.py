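"""End-to-end reproducible pipeline: synth → sensor → beats → features → BP.

A :class:`RunConfig` (YAML- or dict-loadable, unknown keys rejected)
drives the whole chain under one master seed; the run writes every
artifact as CSV/JSON and finishes with a :class:`RunManifest` listing
checksums, per-stage timings and screening counters. Identical configs
produce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bp_classifier as bpc
from . import io as pio
from . import quality_features as qf
from . import synth
from .forward_model import simulate_session

__version__ = "0.1.0"

STAGES = ("synth", "simulate", "features", "train")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "scg_run"
    n_sessions: int = 24
    session_duration_s: float = 55.0
    heart_rate_bpm: float = 75.0
    rr_jitter_sd_s: float = 0.02
    respiration_depth: float = 0.2
    activity_state: str = "rest"
    mains_amp_v: float = 0.0
    test_fraction: float = 0.3
    sqi_threshold: float = qf.SQI_THRESHOLD
    stages: tuple[str, ...] = STAGES
    verbose: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be ≥ 1")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunManifest:
    config: dict
    version: str
    artifacts: dict[str, str] = field(default_factory=dict)  # path → sha256
    timings_s: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    results: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["config"]["stages"] = list(d["config"]["stages"])
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def featurize_sessions(
    digitized: list,
    records: list,
    cfg: qf.PipelineConfig | None = None,
) -> tuple[list, np.ndarray, np.ndarray, np.ndarray, int]:
    """Window, screen and featurize one digitized signal per BP record.

    Returns (features, X, sbp labels, dbp labels, excluded count) over
    the retained windows.
    """
    cfg = cfg or qf.PipelineConfig()
    feats, labels_s, labels_d = [], [], []
    n_excluded = 0
    for i, (sig, rec) in enumerate(zip(digitized, records)):
        windows, _ = qf.extract_windows(
            sig.voltage_v, sig.fs_hz, [rec.t0_s], records=[rec]
        )
        if not windows:
            n_excluded += 1
            continue
        w = windows[0]
        w.window_id = i
        got, _, excluded = qf.screen_and_featurize([w], cfg)
        if excluded or not got:
            n_excluded += 1
            continue
        feats.append(got[0])
        labels_s.append(rec.sbp_class)
        labels_d.append(rec.dbp_class)
    X = (
        np.array([f.to_array() for f in feats])
        if feats
        else np.empty((0, len(qf.FEATURE_NAMES)))
    )
    return feats, X, np.array(labels_s), np.array(labels_d), n_excluded


def bp_classification_experiment(
    n_sessions: int = 300,
    seed: int = 0,
    test_fraction: float = 0.3,
    mains_amp_v: float = 0.0,
) -> dict:
    """Full synthetic BP study: generate, simulate, screen, train, evaluate.

    Generates ``n_sessions`` resting sessions with planted class effects,
    runs them through the sensor/front-end model and the window pipeline,
    and trains/evaluates both three-class models on a stratified split.
    The held-out accuracies measure recovery of the planted mapping on
    synthetic data — they are not a reproduction of any human-subject
    accuracy.
    """
    import warnings

    sessions, records = synth.generate_bp_dataset(n_sessions, seed=seed)
    digitized = [
        simulate_session(s.samples, s.fs_hz, mains_amp_v=mains_amp_v)
        for s in sessions
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        feats, X, y_s, y_d, n_excluded = featurize_sessions(digitized, records)
    out = {"n_retained": len(feats), "n_excluded": n_excluded}
    for target, y in (("sbp", y_s), ("dbp", y_d)):
        _, report = bpc.train_and_evaluate(X, y, test_fraction, seed=seed)
        out[f"{target}_accuracy"] = report.accuracy
        out[f"{target}_confusion"] = report.confusion
        out[f"{target}_auc"] = {k: r.auc for k, r in report.roc.items()}
        out[f"{target}_n_test"] = report.n_test
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stage subset in order and write a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)

    def log(msg: str) -> None:
        if config.verbose:
            print(f"[scgpipe] {msg}")

    def add_artifact(path) -> None:
        manifest.artifacts[str(path)] = _sha256(path)

    def stage_guard(name):
        class _Guard:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log(f"stage {name} ...")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.timings_s[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _Guard()

    sessions = records = None
    if "synth" in config.stages:
        with stage_guard("synth"):
            base = synth.rest_protocol(
                state=config.activity_state,
                duration_s=config.session_duration_s,
                heart_rate_bpm=config.heart_rate_bpm,
                rr_jitter_sd_s=config.rr_jitter_sd_s,
                respiration_depth=config.respiration_depth,
            )
            sessions, records = synth.generate_bp_dataset(
                config.n_sessions, base_protocol=base, seed=config.seed
            )
            if config.activity_state in ("office", "walking"):
                sessions = [
                    synth.add_activity_artifacts(s, s.protocol) for s in sessions
                ]
            add_artifact(pio.write_bp_records(out / "bp_records.csv", records))
            csv_path, json_path = pio.write_waveform(
                out / "session_000", sessions[0]
            )
            add_artifact(csv_path)
            add_artifact(json_path)
            manifest.counts["sessions"] = len(sessions)
            manifest.counts["beats_synthesized"] = int(
                sum(len(s.onsets_s) for s in sessions)
            )

    digitized = None
    if "simulate" in config.stages:
        if sessions is None:
            raise RuntimeError("simulate stage requires the synth stage")
        with stage_guard("simulate"):
            digitized = [
                simulate_session(
                    s.samples, s.fs_hz, mains_amp_v=config.mains_amp_v
                )
                for s in sessions
            ]
            add_artifact(pio.write_digitized(out / "signal_000.csv", digitized[0]))

    features_by_target = None
    if "features" in config.stages:
        if digitized is None or records is None:
            raise RuntimeError("features stage requires synth and simulate stages")
        with stage_guard("features"):
            cfg = qf.PipelineConfig(sqi_threshold=config.sqi_threshold)
            feats, X, y_s, y_d, n_excluded = featurize_sessions(
                digitized, records, cfg
            )
            add_artifact(pio.write_features_csv(out / "features.csv", feats))
            manifest.counts["windows_retained"] = len(feats)
            manifest.counts["windows_excluded"] = n_excluded
            features_by_target = (X, y_s, y_d)

    if "train" in config.stages:
        if features_by_target is None:
            raise RuntimeError("train stage requires the features stage")
        with stage_guard("train"):
            X, y_s, y_d = features_by_target
            for target, y in (("sbp", y_s), ("dbp", y_d)):
                model, report = bpc.train_and_evaluate(
                    X, y, config.test_fraction, seed=config.seed
                )
                model_path = out / f"model_{target}.json"
                model_path.write_text(
                    json.dumps(bpc.weights_to_dict(model), indent=1)
                )
                add_artifact(model_path)
                report_path = out / f"eval_{target}.json"
                report_path.write_text(
                    json.dumps(
                        {
                            "accuracy": report.accuracy,
                            "confusion": report.confusion.tolist(),
                            "auc": {k: r.auc for k, r in report.roc.items()},
                            "n_test": report.n_test,
                            "test_fraction": config.test_fraction,
                            "seed": config.seed,
                        },
                        indent=1,
                    )
                )
                add_artifact(report_path)
                manifest.results[f"{target}_accuracy"] = report.accuracy
                log(f"{target.upper()} held-out accuracy: {report.accuracy:.3f}")

    manifest.to_json(out / "manifest.json")
    return manifest
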