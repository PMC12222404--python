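import numpy as np
import pytest

from dosekit import DegradationModel, PhantomRecipe, VolumetricImage
from dosekit.phantom import generate_task_triplet


@pytest.fixture(scope="session")
def desk_triplet():
    """One deterministic desk-scale phantom triplet shared across tests."""
    recipe = PhantomRecipe(shape=(40, 40, 40), tumour_radius_mm=15,
                           injected_activity_gbq=0.2, seed=11)
    return generate_task_triplet(recipe, DegradationModel(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def smooth_random_volume(shape, rng, spacing=4.795, smooth=1.5, lo=0.0, hi=100.0):
    """A positive, spatially smooth random dose-like volume."""
    from scipy import ndimage

    raw = ndimage.gaussian_filter(rng.random(shape), smooth)
    raw = (raw - raw.min()) / (raw.max() - raw.min() + 1e-12)
    return VolumetricImage(lo + (hi - lo) * raw, (spacing,) * 3)
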