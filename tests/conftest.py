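import numpy as np
import pytest

from gazesal.maps import AttentionMap, FaceMask, IntensityGrid
from gazesal.synthetic import generate_toy_study


def amap(values, participant="p1", group="clinician", image="img1", stage="raw"):
    return AttentionMap(IntensityGrid(np.asarray(values, dtype=float)),
                        participant_id=participant, group=group,
                        image_id=image, stage=stage)


@pytest.fixture(scope="session")
def tiny_study():
    """Small synthetic study reused across tests (3+3 participants, 4 images)."""
    return generate_toy_study(42, n_clin=3, n_nonclin=3, n_images=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def full_mask():
    def make(shape):
        return FaceMask(np.ones(shape, dtype=bool))
    return make
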