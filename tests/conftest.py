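import numpy as np
import pytest

import paraspinal as pp


@pytest.fixture(scope="session")
def grade1_phantom():
    """A seeded moderate-infiltration phantom shared across tests."""
    spec = pp.preset_for_grade(1, seed=7)
    image, truth = pp.generate_phantom(spec)
    return image, truth


@pytest.fixture(scope="session")
def grade1_rater_masks(grade1_phantom):
    _, truth = grade1_phantom
    params = pp.RaterSimParams(n_raters=3, boundary_sd_px=2.0, seed=11)
    return pp.simulate_rater_masks(truth, params, subject_id="s001")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
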