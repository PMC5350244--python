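import numpy as np
import pytest

from slopesync import CycleTemplate, DetectionParams, PopulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def trapezoid_template():
    """Noise-friendly plateau-dominant template: 600-sample period at 1.5 ms,
    80-sample ramps (tau = 40 recovers exact ramp midpoints)."""
    return CycleTemplate(period=900.0, ramp_up=120.0, plateau=360.0, ramp_down=120.0)


@pytest.fixture
def fast_template():
    """Shorter 300-sample period used inside replicate loops."""
    return CycleTemplate(period=450.0, ramp_up=90.0, plateau=180.0, ramp_down=90.0)


@pytest.fixture
def detection_params():
    return DetectionParams(tau=40)


def make_pair_config(template, seed, jitter_sd=3.0, n_cycles=60, noise_sigma=0.02):
    return PopulationConfig(
        seed=seed,
        n_neurons=2,
        template=template,
        n_cycles=n_cycles,
        jitter_sd=jitter_sd,
        noise_sigma=noise_sigma,
        phase_offsets=(0.0, 12.0),
    )
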