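import numpy as np
import pytest

from co2asl.phantom import DEFAULT_CONDITIONS, PhantomSpec


@pytest.fixture
def noiseless_spec() -> PhantomSpec:
    """Default phantom with noise switched off (analysis is exact on it)."""
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture
def default_spec() -> PhantomSpec:
    """Default phantom (noise_sd 20 a.u., seed fixed)."""
    return PhantomSpec(seed=42)


@pytest.fixture
def null_spec() -> PhantomSpec:
    """Phantom with zero injected gains everywhere (pure noise)."""
    zeros = {c: 0.0 for c in DEFAULT_CONDITIONS}
    return PhantomSpec(seed=42, global_gain=zeros, roi_gain=zeros)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
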