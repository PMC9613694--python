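import numpy as np
import pytest

from linlaw.synthetic import DistortionSpec, make_class_models, simulate_panel


@pytest.fixture(scope="session")
def clean_panel():
    """Noiseless c=3, m=2 panel with distinct order-2 recurrences per class."""
    models = make_class_models(c=3, m=2, order=2, seed=7)
    return simulate_panel(models, counts=[6, 6, 6], k=120, seed=7)


@pytest.fixture(scope="session")
def clean_models():
    return make_class_models(c=3, m=2, order=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_small_panel():
    """6-instance, 2-channel, 2-class noisy panel for pipeline oracle checks."""
    models = make_class_models(c=2, m=2, order=2, seed=3)
    return simulate_panel(
        models,
        counts=[3, 3],
        k=60,
        distortions=DistortionSpec(noise_sigma=0.1),
        seed=3,
    )
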