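"""Shared fixtures: small phantoms and helpers for grid construction.

Phantoms used by the unit tests are 64^3 at 3.5 mm spacing (~1.4 L lungs,
~30k lung voxels): large enough for stable histogram statistics, small
enough that the whole suite stays fast.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from lungdens import CTVolume, LungMask, PhantomSpec, generate_phantom

# phantom parenchyma tails below -1024 HU are expected; silence that logger
logging.getLogger("lungdens.volume_io").setLevel(logging.ERROR)

SMALL = dict(shape=(64, 64, 64), spacing=(3.5, 3.5, 3.5))


def flat_volume(values, shape=None, spacing=(1.0, 1.0, 1.0)) -> tuple[CTVolume, LungMask]:
    """A volume holding ``values`` (any order) with an all-ones mask."""
    values = np.asarray(values, dtype=np.float64)
    if shape is None:
        shape = (values.size, 1, 1)
    vol = CTVolume(values.reshape(shape), spacing)
    mask = LungMask(np.ones(shape, dtype=np.int32), {1: "lung"}, spacing)
    return vol, mask


@pytest.fixture(scope="session")
def clean_phantom():
    """Lesion-free phantom: pure parenchyma + vessels."""
    return generate_phantom(PhantomSpec(**SMALL, lesion_fraction=0.0, seed=11))


@pytest.fixture(scope="session")
def diseased_phantom():
    """Phantom with 8% lesion burden, spatially unbiased."""
    return generate_phantom(PhantomSpec(**SMALL, lesion_fraction=0.08, seed=11))


@pytest.fixture(scope="session")
def lower_lesion_phantom():
    """Phantom with all lesions seeded in the caudal half."""
    return generate_phantom(PhantomSpec(**SMALL, lesion_fraction=0.08, lesion_lower_bias=1.0, seed=11))
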