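import numpy as np
import pytest

from petdose.phantom import AcquisitionMeta, PhantomGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_geometry():
    """A shrunken torso/liver layout for fast phantom tests."""
    return PhantomGeometry(
        shape=(48, 48, 36),
        voxel_size=(4.1, 4.1, 3.0),
        liver_semiaxes=(60.0, 50.0, 40.0),
        liver_offset=(10.0, 0.0, 0.0),
        torso_semiaxes=(90.0, 80.0, 200.0),
    )


@pytest.fixture
def reference_meta():
    """Full acquisition of the mean-habitus subject at 1.5 MBq/kg."""
    return AcquisitionMeta(activity=1.5 * 86.5, mbp=6.0)
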