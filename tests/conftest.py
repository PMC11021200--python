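import numpy as np
import pytest

from bodyquant import LabelVolume, VolumeGrid

DEFAULT_SPACING = (10.0, 6.5, 6.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mask(arr, spacing=DEFAULT_SPACING) -> LabelVolume:
    return LabelVolume(np.asarray(arr, dtype=np.uint8), spacing)


def make_volume(arr, spacing=DEFAULT_SPACING) -> VolumeGrid:
    return VolumeGrid(np.asarray(arr, dtype=float), spacing)
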