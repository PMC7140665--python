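import numpy as np
import pytest

from epifish import calcium_dff, synthetic
from epifish.lfp_power import LFPTrace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_trace():
    g = np.random.default_rng(7)
    return LFPTrace(samples=g.standard_normal(50_000) * 20.0,
                    sampling_rate=5000.0)


@pytest.fixture(scope="session")
def small_stack():
    """64x64, 200-frame noisy stack with no planted structure."""
    g = np.random.default_rng(11)
    px = 100.0 + g.standard_normal((200, 64, 64)) * 5.0
    return calcium_dff.FluorescenceStack(pixels=px, frame_rate=4.0)


@pytest.fixture(scope="session")
def domain_recording():
    """Paired LFP + movie with burst-locked Cb domains (session cache)."""
    lfp, lgt = synthetic.gen_lfp(90, n_bursts=8, burst_duration=1.5,
                                 burst_delta=1.0, seed=4)
    bf = np.round(lgt.burst_times * 4).astype(int)
    specs = [{"region": "Cb", "area": 45, "duration": 8, "t0": int(f)}
             for f in bf]
    stack, gt, atlas = synthetic.gen_movie(dims=(128, 128), frames=360,
                                           lfp_gt=lgt, domain_spec=specs,
                                           snr=3.0, seed=5)
    return lfp, stack, gt, atlas
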