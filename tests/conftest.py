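import numpy as np
import pytest

from meniscometry import (
    LabelVolume,
    default_knee_spec,
    generate_knee,
)


@pytest.fixture(scope="session")
def non_dlm_knee():
    """One crescent-lateral-meniscus phantom (volume, truth, spec), noise-free."""
    spec = default_knee_spec("non_dlm", seed=11)
    vol, truth = generate_knee(spec)
    return vol, truth, spec


@pytest.fixture(scope="session")
def complete_dlm_knee():
    """One complete-discoid phantom (coverage 1, no gap)."""
    spec = default_knee_spec("complete_dlm", seed=12)
    vol, truth = generate_knee(spec)
    return vol, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kwargs):
    """Small axis-aligned LabelVolume helper for unit tests."""
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = spacing[i]
        aff[i, 3] = origin[i]
    return LabelVolume(voxels=np.asarray(voxels), affine=aff, **kwargs)
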