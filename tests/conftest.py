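import dataclasses

import numpy as np
import pytest

from glioseg.phantom import Ellipsoid, PhantomSpec, default_specs, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The low-noise default phantom: (study, truth, tissue maps)."""
    return generate_phantom(default_specs()["low-noise"])


def small_phantom_spec(noise_seed: int = 0) -> PhantomSpec:
    """A 48^3 phantom with the same nested anatomy, for fast end-to-end tests."""
    return dataclasses.replace(
        default_specs()["low-noise"],
        name="small",
        shape=(48, 48, 48),
        brain=Ellipsoid((24, 24, 24), (19, 18, 17)),
        wm=Ellipsoid((24, 24, 24), (15, 13, 12)),
        csf=Ellipsoid((14, 26, 25), (3, 3, 3)),
        tumour_center=(28.0, 24.0, 24.0),
        tumour_radii=(3.5, 5.0, 6.5, 8.0),
        noise_seed=noise_seed,
    )


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(7)
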