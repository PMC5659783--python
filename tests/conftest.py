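import numpy as np
import pytest

from vssm import FITTED_PARAMS, ModelParams, SimConfig


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def fitted():
    """Bundled fitted parameter sets, keyed by model id."""
    return FITTED_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_params(model_id: str, **overrides) -> ModelParams:
    """A valid parameter set for any model, with optional overrides."""
    base = {"b": 1.0, "g": 0.2, "sigma": 2.0}
    extras = {"i_v": 0.5, "s": 2.0, "i_d": 0.02, "a": 1.3}
    from vssm import ACTIVE_PARAMS
    kwargs = dict(base)
    for name in ACTIVE_PARAMS[model_id]:
        if name in extras:
            kwargs[name] = extras[name]
    kwargs.update(overrides)
    return ModelParams(model_id=model_id, **kwargs)
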