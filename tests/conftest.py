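import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast synthetic venome: few transcripts, shallow library."""
    from venomecorr import GeneratorConfig

    return GeneratorConfig(
        n_transcripts=20,
        length_range_nt=(240, 600),
        total_fragments=50_000,
        n_contaminants=4,
        detection_noise_sigma=0.0,
        seed=11,
    )
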