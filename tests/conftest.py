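import numpy as np
import pytest

from retinal_sampling.network import SamplingSpec, SurrogateV1Config, build_surrogate_v1


@pytest.fixture(scope="session")
def small_spec():
    """Small resampling geometry with odd rasters (exact center pixels)."""
    return SamplingSpec(input_width=129, output_width=65, fov=20.0)


@pytest.fixture(scope="session")
def small_adapter():
    """Cheap no-RSL surrogate for analysis-plumbing tests."""
    spec = SamplingSpec(input_width=64, output_width=64, fov=20.0)
    return build_surrogate_v1(SurrogateV1Config(sampling=spec, include_rsl=False))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
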