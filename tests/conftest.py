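import os

# many small float64 matmuls: BLAS thread fan-out only adds contention
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsecast import SignalTrace, SynthConfig, TransferConfig
from pulsecast.synthgen import gen_components

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def sine_trace() -> SignalTrace:
    """1 Hz unit sine, fs = 100 Hz, 10 s."""
    t = np.arange(1000) / 100.0
    return SignalTrace(samples=np.sin(2 * np.pi * t), fs=100.0, label="sine")


@pytest.fixture
def clean_synth_cfg() -> SynthConfig:
    """Artifact-free pulse train: jitterless inspection config."""
    return SynthConfig(
        duration_s=30.0,
        hr_bpm=60.0,
        hr_jitter=0.0,
        resp_depth=0.0,
        drift_amp=0.0,
        spike_rate_hz=0.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_synth_cfg() -> SynthConfig:
    """Default-condition noisy config used by the denoising tests."""
    return SynthConfig(duration_s=30.0, seed=3)


@pytest.fixture
def clean_pulse_trace(clean_synth_cfg) -> SignalTrace:
    return gen_components(clean_synth_cfg)["clean"]


@pytest.fixture
def identity_transfer() -> TransferConfig:
    return TransferConfig(
        delay_s=0.0, smoothing_tau_s=0.0, gain=1.0, nonlin_coeff=0.0, target_noise_sd=0.0
    )
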