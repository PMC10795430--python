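import numpy as np
import pytest

from gateqa.acquisition import AcquisitionModel, sample_trace
from gateqa.breathing import BreathingTrace, Cos4Spec, generate_pattern
from gateqa.gating import GateWindow, gate_signal

REFERENCE = Cos4Spec(amplitude=20.0, period=4.0, duration=60.0)


@pytest.fixture(scope="session")
def cos4_trace() -> BreathingTrace:
    """Noise-free reference waveform: 20 mm peak-to-peak, 4 s period, 60 s."""
    return generate_pattern(REFERENCE)


@pytest.fixture(scope="session")
def measured_trace(cos4_trace) -> BreathingTrace:
    """Noise-free camera resampling of the reference waveform."""
    return sample_trace(cos4_trace, AcquisitionModel(noise_sd=0.0), seed=7)


@pytest.fixture(scope="session")
def reference_gate(cos4_trace):
    """Gate for the 30% exhale – 30% inhale window on the reference trace."""
    return gate_signal(cos4_trace, GateWindow(30.0, 30.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
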