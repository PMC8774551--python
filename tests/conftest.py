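import numpy as np
import pytest

from crte import (
    ProcessSpec,
    exponential_model,
    generate,
    get_kernel,
    make_bandwidths,
)


@pytest.fixture(scope="session")
def gaussian():
    return get_kernel("gaussian")


@pytest.fixture(scope="session")
def exp_model():
    return exponential_model(1.0)


@pytest.fixture
def exp_sample():
    """One seeded i.i.d. unit-rate exponential sample factory."""

    def _make(n, seed=11, stream=0):
        spec = ProcessSpec(family="iid", marginal="exponential",
                           marginal_params={"lam": 1.0}, n=n,
                           seed=seed, stream=stream)
        return generate(spec)

    return _make


@pytest.fixture
def bw_factory():
    def _make(n, c=1.0, theta=0.5):
        return make_bandwidths(c, theta, n)

    return _make
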