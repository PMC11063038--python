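import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rflpkit import GelParams, build_reference_profiles, digest
from rflpkit.fixtures import ASEI, apis_panel, apis_templates

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def apis():
    """The bundled six-species synthetic Apis amplicon panel."""
    return apis_panel()


@pytest.fixture(scope="session")
def apis_temps():
    """The Apis amplicons embedded in random template flanks."""
    return apis_templates()


@pytest.fixture(scope="session")
def apis_profiles(apis):
    """AseI reference profile set for the six-species panel, default gel."""
    return build_reference_profiles([(r.species, digest(r, ASEI)) for r in apis])


@pytest.fixture
def gel():
    return GelParams()


def random_seq(rng: np.random.Generator, n: int, forbidden: tuple[str, ...] = ()) -> str:
    """Random ACGT string rejected until it contains none of ``forbidden``."""
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if not any(f in seq for f in forbidden):
            return seq
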