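import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibtreat.model import LatentConfig, ModelParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_params() -> ModelParams:
    """A small random model: 3 x1 columns, 2 x2 columns, k=(3, 2), narrow nets."""
    return ModelParams.init(
        d1=3, d2=2,
        latent=LatentConfig(k1=3, k2=2, embed_dim=2),
        outcome_family="gaussian", seed=7, hidden=8, depth=3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_linear_head(slope: np.ndarray, intercept: float):
    """Single affine layer usable as a decoder head (z -> slope.z + intercept)."""
    from ibtreat._autodiff import Tensor

    w = np.asarray(slope, dtype=np.float64).reshape(-1, 1)
    return [(Tensor(w, requires_grad=True),
             Tensor(np.array([intercept]), requires_grad=True))]
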