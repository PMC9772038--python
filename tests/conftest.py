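import numpy as np
import pytest

from abikit.phantom import PhantomConfig, SourceSpec, TransducerSpec


@pytest.fixture
def single_source_config():
    """Noiseless, leak-free single 8 Hz source at the origin."""

    def make(frequency=8.0, amplitude=100.0, noise_sd=0.0, lf_leak_gain=0.0,
             seed=0, **kwargs):
        return PhantomConfig(
            sources=(SourceSpec(position=(0.0, 0.0), frequency=frequency,
                                amplitude=amplitude),),
            transducer=TransducerSpec(),
            noise_sd=noise_sd,
            lf_leak_gain=lf_leak_gain,
            seed=seed,
            **kwargs,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
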