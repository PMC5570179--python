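import numpy as np
import pytest

from pocketdyn.binding_site import define_site_from_point
from pocketdyn.fixtures import ToyEnsembleSpec, make_shell_structure


@pytest.fixture(scope="session")
def shell_spec():
    return ToyEnsembleSpec(hollow_radius=5.0, wall_spacing=3.0)


@pytest.fixture(scope="session")
def shell(shell_spec):
    return make_shell_structure(shell_spec)


@pytest.fixture(scope="session")
def shell_site(shell, shell_spec):
    # wall atoms start ~hollow_radius + 3 A out; radius reaches the inner layer
    return define_site_from_point(shell, (0.0, 0.0, 0.0),
                                  radius=shell_spec.hollow_radius + 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
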