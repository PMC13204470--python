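import pytest

import scgpipe as sp


@pytest.fixture(scope="session")
def breath_hold_session():
    """Clean 60 s breath-hold session at 60 bpm, zero jitter."""
    return sp.generate_session(sp.breath_hold_protocol(duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def rest_session():
    """60 s resting session at 75 bpm with default jitter and respiration."""
    return sp.generate_session(sp.rest_protocol(duration_s=60.0, seed=12))


@pytest.fixture(scope="session")
def digitized_breath_hold(breath_hold_session):
    w = breath_hold_session
    return sp.simulate_session(w.samples, w.fs_hz)


@pytest.fixture(scope="session")
def digitized_rest(rest_session):
    w = rest_session
    return sp.simulate_session(w.samples, w.fs_hz)


def run_beat_pipeline(voltage, fs):
    """Convenience: enhancement → envelope → detection → RR."""
    enhanced = sp.bandpass_enhance(voltage, fs)
    env = sp.rms_envelope(enhanced, fs)
    beats = sp.detect_beats(env)
    rr, hr = sp.rr_intervals(beats)
    return beats, rr, hr


@pytest.fixture(scope="session")
def clean_template(breath_hold_session):
    """Template built from ground-truth onsets of a clean session."""
    w = breath_hold_session
    segments, _ = sp.segment_beats(
        w.samples, w.fs_hz, w.onsets_s, window_s=(0.0, 0.5)
    )
    return sp.build_template(segments, w.fs_hz, start_s=0.0)
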