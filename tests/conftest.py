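import numpy as np
import pytest

from ventriflow import VentricleSimParams, ejection_peak_flow, generate_flow_trace


def make_params(rate=60.0, sv=10.0, noise_frac=0.0, seed=0, duration=30.0,
                **kw):
    """Simulator params with noise given as a fraction of the ejection peak."""
    base = VentricleSimParams(
        beat_rate=rate, stroke_volume=sv, duration=duration, seed=seed, **kw
    )
    if noise_frac == 0.0:
        return base
    from dataclasses import replace

    return replace(base, noise_sd=noise_frac * ejection_peak_flow(base))


@pytest.fixture
def params_factory():
    return make_params


@pytest.fixture
def clean_trace():
    """Noise-free 60 bpm / 10 nL trace at the default 50 Hz, 30 s."""
    return generate_flow_trace(make_params())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
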