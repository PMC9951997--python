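"""Shared fixtures: small phantoms and conditioned pairs (session-scoped)."""

import numpy as np
import pytest

from mrisct import phantom, preprocess
from mrisct.volume import ImageVolume


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(grid_shape=(32, 96, 96), spacing=(3.0, 2.0, 2.0), seed=7)


@pytest.fixture(scope="session")
def phantom_pair(small_spec):
    return phantom.generate_pair(small_spec)


@pytest.fixture(scope="session")
def conditioned_pair(phantom_pair):
    ct, mri, labels = phantom_pair
    ct_c = preprocess.prepare_ct(ct, mri)
    mri_c = preprocess.prepare_mri(mri)
    return ct_c, mri_c, labels


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality="CT", background=None):
    values = np.asarray(values, dtype=np.float64)
    return ImageVolume(values=values, spacing=spacing, origin=(0.0, 0.0, 0.0),
                       modality=modality, background_mask=background)
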