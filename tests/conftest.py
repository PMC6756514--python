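from types import SimpleNamespace

import numpy as np
import pytest

from lagstruct.lagmap import track
from lagstruct.preprocess import bandpass
from lagstruct.synth import SynthSpec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tracked_run():
    """A mid-size noisy synthetic run with its tracked lag structure.

    Shared across modules to avoid re-tracking: default axial delay gradient
    over +/-4 s, 1% sLFO, 0.3% thermal noise, 900 frames at TR 0.5 s.
    """
    spec = SynthSpec(shape=(16, 16, 6), n_frames=900, slfo_amplitude_pct=1.0,
                     noise_sd_pct=0.3, rng_seed=42)
    vol, truth = simulate(spec)
    X = vol.to_matrix()
    Xb = bandpass(X, 0.008, 0.07, 0.5)
    ls = track(Xb, 0.5, range_s=4.0)
    return SimpleNamespace(spec=spec, vol=vol, truth=truth, X=X, Xb=Xb, ls=ls)
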