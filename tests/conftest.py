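import numpy as np
import pytest

from thetagamma import synth
from thetagamma.core import Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free, drift-free, line-free coupled signal config."""
    return synth.SynthConfig(duration_s=4.1, coupling_depth=0.0, theta_phase_drift=0.0,
                             noise_amp_uv=0.0, line_amp_uv=0.0, seed=0)


def make_epoch(samples, fs_hz=2000.0, label="pre", index=0):
    return Epoch(samples=np.asarray(samples, dtype=float), fs_hz=fs_hz,
                 window_label=label, sub_window_index=index, start_s=0.0)


@pytest.fixture
def coupled_epoch_factory():
    """Epoch of a coupled theta-gamma signal with the default background."""

    def factory(depth=0.6, seed=0, duration_s=4.1, **kwargs):
        cfg = synth.SynthConfig(duration_s=duration_s, coupling_depth=depth,
                                seed=seed, **kwargs)
        rec = synth.gen_coupled_eeg(cfg)
        return make_epoch(rec.samples, fs_hz=cfg.fs_hz)

    return factory
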