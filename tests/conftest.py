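import numpy as np
import pytest

import lesiondecode as ld


@pytest.fixture(scope="session")
def atlas():
    """Default 32^3 atlas with 10 mirrored region pairs plus CST pair."""
    return ld.make_atlas((32, 32, 32), n_region_pairs=10, seed=0)


@pytest.fixture(scope="session")
def small_atlas():
    return ld.make_atlas((16, 16, 16), n_region_pairs=3, seed=1,
                         region_radius_range=(1.5, 2.5))


@pytest.fixture(scope="session")
def cohort(atlas):
    """A prepared 30-subject cohort with clear damage signal."""
    probs, scores, truth = ld.simulate_cohort(
        atlas, 30, seed=11, noise_sd=2.0, effect_scale=3.0
    )
    functional = ld.make_functional_mask(atlas, seed=12)
    c = ld.prepare_cohort(atlas, probs, scores, functional_mask=functional)
    c._truth = truth  # stashed for recovery checks
    return c


def cube_volume(shape, corner, size, value=0.9):
    """A probability volume holding one solid cube."""
    vol = np.zeros(shape)
    x, y, z = corner
    vol[x : x + size[0], y : y + size[1], z : z + size[2]] = value
    return ld.LesionProbabilityVolume(probabilities=vol, subject_id="cube")
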