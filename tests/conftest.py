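import numpy as np
import pytest
from hypothesis import settings

from robustchange.models import ModelSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def fast_spec():
    """Small MCMC budget for unit tests; posterior summaries stay usable."""
    def make(kind="single_group", **kw):
        defaults = dict(
            model_kind=kind, chains=4, draws_per_chain=800, warmup=300, seed=99
        )
        defaults.update(kw)
        return ModelSpec(**defaults)
    return make
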