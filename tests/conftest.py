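import numpy as np
import pytest

from foldshift import synthetic_data


@pytest.fixture
def noiseless_melt():
    """A clean two-state melt with distinct baselines (dH=40, Tm=58 degC)."""
    return synthetic_data.gen_melt(dH=40.0, Tm_c=58.0, Yn=-12.0, Mn=0.01, Yd=-2.0, Md=-0.005)


@pytest.fixture
def gaussian_spectrum():
    def _make(center=336.5, height=1000.0, noise_sd=0.0, seed=0, **kw):
        return synthetic_data.gen_emission(
            lambda_max=center, F_max=height, noise_sd=noise_sd, seed=seed, **kw
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
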