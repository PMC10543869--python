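import pytest

from bednetopt import (
    Economics,
    EvolutionParams,
    InsecticideProfile,
    NetPhysicalProfile,
    load_and_validate,
)


@pytest.fixture(scope="session")
def ins_fast():
    """A potent, fast-decaying test insecticide."""
    return InsecticideProfile(name="fast", d_c=0.5, d_m=-1.0, h_m=4.0, k=2.0)


@pytest.fixture(scope="session")
def ins_cheap():
    """A cheap partner with pre-existing resistance (pyrethroid-like)."""
    return InsecticideProfile(
        name="cheap", d_c=0.7, d_m=-1.2, h_m=3.0, k=0.3, initial_steps=3
    )


@pytest.fixture(scope="session")
def phys():
    return NetPhysicalProfile(u=0.9, d_p=-0.7, h_p=2.5, a=1.5)


@pytest.fixture(scope="session")
def econ():
    return Economics(budget=2.0)


@pytest.fixture(scope="session")
def evo():
    return EvolutionParams(r=1.0, K=1e6, mu=5e-8, d_q=0.5, f_init=1e-3)


@pytest.fixture(scope="session")
def default_cfg():
    """The packaged default configuration."""
    return load_and_validate()


@pytest.fixture()
def small_overrides():
    """A coarse, quick grid for sweep tests."""
    return {
        "grid": {
            "loading_max": 1.0,
            "loading_interval": 0.5,
            "lifespan_max": 3.0,
            "lifespan_interval": 1.0,
        }
    }
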