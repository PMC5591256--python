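import numpy as np
import pytest

from triplexkit import builder, oligo

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def catalog():
    return oligo.load_catalog()


@pytest.fixture(scope="session")
def ds19():
    return oligo.get_duplex("c-MYC_DS19")


@pytest.fixture(scope="session")
def ds19_hetero():
    return oligo.get_duplex("c-MYC_DS19Hetero")


@pytest.fixture(scope="session")
def on2_5dna():
    return oligo.get_oligo("ON2-5′DNA")


@pytest.fixture(scope="session")
def b_duplex(ds19):
    """Canonical B-form fiber model of the 19-bp c-MYC duplex."""
    return builder.build_duplex(ds19, builder.HelixParamsSpec.b_form())


@pytest.fixture(scope="session")
def triplex(ds19, on2_5dna):
    """B-form triplex: c-MYC 19-mer duplex with the ON2-5'DNA TFO."""
    return builder.build_triplex(ds19, on2_5dna, builder.HelixParamsSpec.b_form())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(99)).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t
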