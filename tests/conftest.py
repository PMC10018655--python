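import numpy as np
import pytest

from ctiq import (ImageStack, LatentRatingModel, PhantomConfig, Question,
                  RatingDesign, Structure, generate_ratings)
from ctiq.vgc import OrientedRatings


@pytest.fixture
def small_phantom():
    """128 px phantom with an aorta-like disk and a fat-like disk, wide FOV."""
    structures = [
        Structure("disk", (0.0, 8.0), 30.0, 45.0),
        Structure("disk", (0.0, -25.0), 24.0, -100.0),
    ]
    return PhantomConfig(image_size=128, pixel_spacing=1.0, n_slices=3,
                         body_axes=(120.0, 110.0), body_hu=30.0,
                         structures=structures)


@pytest.fixture
def flat_stack():
    """Zero-HU stack large enough for the default ROI tiling."""
    return ImageStack(np.zeros((4, 128, 128)), pixel_spacing=0.75)


@pytest.fixture
def single_question_design():
    def make(scale_size=5, n_cases=25, n_readers=5):
        return RatingDesign(n_cases=n_cases, n_readers=n_readers,
                            questions=[Question("Q1", scale_size)],
                            conditions=("reference", "test"))
    return make


@pytest.fixture
def rating_set_factory(single_question_design):
    def make(delta=0.0, seed=0, scale_size=5, n_cases=25, n_readers=5,
             sigma_case=0.5, sigma_reader=0.3):
        design = single_question_design(scale_size, n_cases, n_readers)
        model = LatentRatingModel(delta=delta, sigma_case=sigma_case,
                                  sigma_reader=sigma_reader)
        return generate_ratings(design, model, seed=seed)
    return make


def oriented_from_lists(test, reference, scale_size):
    """Build OrientedRatings from flat paired lists (one pseudo-reader)."""
    t = np.asarray(test, dtype=int).reshape(-1, 1)
    r = np.asarray(reference, dtype=int).reshape(-1, 1)
    return OrientedRatings(test_matrix=t, reference_matrix=r, scale_size=scale_size,
                           case_ids=list(range(len(t))), reader_ids=["r1"])


def pairwise_auc_oracle(test, reference):
    """Independent oracle: explicit loop over all test x reference pairs,
    wins + half credit for ties."""
    total = 0.0
    for t in test:
        for r in reference:
            if t > r:
                total += 1.0
            elif t == r:
                total += 0.5
    return total / (len(test) * len(reference))
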