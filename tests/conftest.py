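import numpy as np
import pytest

from scapmorph.synthetic import ScapulaParams, generate_scapula


@pytest.fixture(scope="session")
def default_scapula():
    """Default-parameter right scapula with analytic ground truth."""
    return generate_scapula(ScapulaParams(seed=1))


@pytest.fixture(scope="session")
def neutral_params():
    """Parameters with every orientation at its neutral value.

    The neutral acromial plate has its longitudinal axis along ŷ (SPAA = 90°
    raw) and the neutral spine axis points along −x̂ (APSSA = −90° raw);
    SPSSA is left at a small roll so the spine stays measurable.
    """
    return ScapulaParams(
        gi_deg=0.0, gv_deg=0.0,
        cpaa_deg=0.0, spaa_deg=90.0, apaa_deg=0.0,
        cpssa_deg=30.0, spssa_deg=0.0, apssa_deg=-90.0,
        acromion_corner_trim=0.0,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_rigid(rng):
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50.0, 50.0, 3)
    return R, t
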