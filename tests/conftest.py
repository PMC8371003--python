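import pytest

from reeffishery import Parameters


@pytest.fixture
def make_params():
    """Factory for the reference parameter set with per-test overrides.

    Defaults: no reef (V=0), no illegal effort, strong attraction/production
    variant (beta0=1, delta_k=5).
    """

    def factory(**overrides):
        base = dict(V=0.0, gamma=0.0, beta0=1.0, delta_k=5.0)
        base.update(overrides)
        return Parameters(**base)

    return factory
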