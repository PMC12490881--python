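import numpy as np
import pytest

from semgdec.synthetic import (
    GestureTemplateSet,
    NoiseModel,
    ProtocolConfig,
    default_templates,
    make_protocol,
    make_session,
)


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """A 3-gesture, 2-repetition protocol that keeps signals short."""
    return ProtocolConfig(
        n_gestures=3, n_repetitions=2, hold_duration=1.5, pause_duration=0.8
    )


@pytest.fixture(scope="session")
def templates() -> GestureTemplateSet:
    return default_templates()


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseModel:
    """No line hum, no artifacts: the cleanest synthesis path."""
    return NoiseModel(line_freqs={}, baseline_sd=0.5, artifact_rate=0.0)


@pytest.fixture(scope="session")
def small_bundle(small_protocol, quiet_noise):
    """One short synthetic session at a reduced sampling rate."""
    return make_session(
        small_protocol, noise=quiet_noise, fs=2000.0, kin_rate=120.0, seed=11
    )


@pytest.fixture(scope="session")
def small_annotation(small_protocol):
    return make_protocol(small_protocol)
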