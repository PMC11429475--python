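import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from glaucovit.labels import GLAUCOMA, NORMAL, SUSPECT
from glaucovit.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless, vessel-free phantom spec with known geometry."""
    return PhantomSpec(
        image_size=64, disc_center=(32.0, 32.0), disc_radius=20.0,
        cup_to_disc_ratio=0.7, n_vessels=0, noise_sigma=0.0,
        illumination_slope=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def small_phantom_set():
    """Three-class noisy phantom set: 12 images per class at 32x32."""
    spec = PhantomSpec(image_size=32, disc_center=(16, 16), disc_radius=7,
                       noise_sigma=3.0, n_vessels=2)
    manifest, images = generate_dataset(
        {GLAUCOMA: 12, NORMAL: 12, SUSPECT: 12}, spec, seed=7
    )
    return manifest, images


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
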