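import numpy as np
import pytest

from valvemech import mechanics, synthetic


@pytest.fixture
def post_geometry():
    """The device's standard posts: 2 mm diameter, 6 mm length, 1 MPa elastomer."""
    return mechanics.PostGeometry(
        diameter=2e-3, length=6e-3, elastic_modulus=1e6, base_separation=500e-6
    )


@pytest.fixture
def tissue_model():
    """Reference Fung tissue: alpha = 20 kPa, beta = 8, 1 mm x 40 um x 500 um strip."""
    return synthetic.TissueModel(
        alpha=0.02e6, beta=8.0, width=1e-3, thickness=40e-6, rest_length=500e-6
    )


@pytest.fixture
def stretch_levels():
    return np.arange(1.0, 1.601, 0.1)
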