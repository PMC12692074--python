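import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def normal_mean_params():
    """Geometry targets reproducing the normal-group mean angles."""
    from sagspine.synthetic import GeometryParams

    return GeometryParams(ba=0.389, arc_extent=85.0, sacral_orientation=39.4,
                          t12_tilt=26.0, sacral_tilt=50.3,
                          pelvic_incidence=56.8, noise_sd=0.0)


@pytest.fixture
def normal_mean_spine(normal_mean_params):
    from sagspine.synthetic import spine_from_params

    ls, truth = spine_from_params(normal_mean_params, subject_id="nm",
                                  group="normal")
    return ls, truth
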