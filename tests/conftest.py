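import numpy as np
import pytest

from tofsaa import (
    PhantomSpec,
    ScanGeometry,
    TOFModel,
    build_system_operators,
    make_phantom,
    mean_data,
)


@pytest.fixture(scope="session")
def geom16():
    return ScanGeometry(grid_n=16, fov_cm=30.0, n_views=16, n_rays=16)


@pytest.fixture(scope="session")
def tof16():
    return TOFModel(fwhm_cm=4.5, n_windows=5)


@pytest.fixture(scope="session")
def ops16(geom16, tof16):
    return build_system_operators(geom16, tof16, seed=0)


@pytest.fixture(scope="session")
def geom32():
    return ScanGeometry(grid_n=32, fov_cm=30.0, n_views=32, n_rays=32)


@pytest.fixture(scope="session")
def tof32():
    return TOFModel(fwhm_cm=4.5, n_windows=7)


@pytest.fixture(scope="session")
def ops32(geom32, tof32):
    return build_system_operators(geom32, tof32, seed=0)


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(PhantomSpec(grid_n=32))


@pytest.fixture(scope="session")
def problem32(ops32, phantom32):
    """Truth images, operators and noiseless mean data at 32x32."""
    act, att = phantom32
    c = mean_data(act, att, ops32)
    return {"act": act, "att": att, "ops": ops32, "c": c,
            "Ntotal": float(act.sum())}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
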