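import dataclasses

import numpy as np
import pytest

from tomoqa.acquisition import AcquisitionModel
from tomoqa.geometry import BeadRamp, PhantomGeometry, default_geometry
from tomoqa.simulate import render


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def default_acq():
    return AcquisitionModel(seed=1)


@pytest.fixture(scope="session")
def default_volume(geom, default_acq):
    """Full default phantom render with default noise (seed 1)."""
    return render(geom, default_acq)


@pytest.fixture(scope="session")
def noiseless_volume(geom):
    return render(geom, AcquisitionModel(noise_base_sd=0.0))


@pytest.fixture(scope="session")
def ramp():
    """A single folded ramp set centred in a compact geometry."""
    return BeadRamp(ramp_id="ramp", side="left", lateral_position=0.0,
                    y_start=8.0)


@pytest.fixture(scope="session")
def ramp_geom(ramp):
    """Compact ramp-only geometry for fast slice-profile sweeps."""
    return PhantomGeometry(x_range=(-6.0, 6.0), y_range=(0.0, 56.0),
                           ramps=(ramp,))


@pytest.fixture(scope="session")
def ramp_volume_factory(ramp_geom):
    """Render (and cache) ramp-only volumes for given acquisition settings."""
    cache = {}

    def factory(**kwargs):
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            cache[key] = render(ramp_geom, AcquisitionModel(**kwargs))
        return cache[key]

    return factory


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def replace_acq(acq, **kwargs):
    return dataclasses.replace(acq, **kwargs)
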