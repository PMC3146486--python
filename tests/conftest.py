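import numpy as np
import pytest

from voxelage.io_cohort import VolumeStack
from voxelage.masking import MaskVolume, build_mask
from voxelage.synthetic import PhantomSpec, SphereRegion, generate_cohort, generate_templates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """Four random 4x4x4 volumes on an identity-affine grid."""
    data = rng.normal(0.5, 0.1, size=(4, 4, 4, 4))
    return VolumeStack(data, np.eye(4), ["s0", "s1", "s2", "s3"])


@pytest.fixture
def full_mask():
    return MaskVolume.full((4, 4, 4))


@pytest.fixture
def default_mask():
    """Mask built from the synthetic box templates at the default threshold."""
    ta, tb = generate_templates((16, 16, 16))
    return build_mask(ta, tb, 0.2)


@pytest.fixture
def phantom_cohort():
    """Age-sloped cohort with a planted atrophy sphere; controls first."""
    spec = PhantomSpec(
        n_controls=30,
        n_patients=30,
        beta_age=-0.003,
        atrophy_delta=-0.05,
        atrophy_region=SphereRegion((8, 8, 8), 3),
        noise_sd=0.02,
        seed=7,
    )
    return generate_cohort(spec)


def control_view(stack, table):
    """(stack, ages) restricted to the control group, original order."""
    idx = np.flatnonzero(table.groups == "control")
    return stack.subset(idx), table.ages[idx]
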