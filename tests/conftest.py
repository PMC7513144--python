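import numpy as np
import pytest

from szcascade import CascadeSpec, mapk_preset, steady_state


@pytest.fixture(scope="session")
def mapk_spec() -> CascadeSpec:
    return mapk_preset()


@pytest.fixture(scope="session")
def mapk_rest(mapk_spec):
    """Resting (sustained-ligand) steady state of the preset."""
    return steady_state(mapk_spec)


@pytest.fixture()
def two_step_spec() -> CascadeSpec:
    """Minimal driver/target cascade with unit rates."""
    return CascadeSpec(
        step_names=("driver", "target"),
        X0=[1.0, 1.0],
        k_fwd=[1.0],
        k_rev=[1.0],
        Ph=[1.0, 1.0],
        A0=1.0,
        ligand=1.0,
        k_on=1.0,
        k_off=1.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
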