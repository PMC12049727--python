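import numpy as np
import pytest

from lamellometer import TfiParams, make_phantom


@pytest.fixture(scope="session")
def tfi_params():
    """Blue-channel reflectivity model at the cryo stage temperature."""
    return TfiParams(wavelength_nm=463.0, r_mea=1.0, r_A=0.5)


@pytest.fixture(scope="session")
def thin_phantom():
    """430 nm lamella phantom (the thin-lamella reference geometry)."""
    return make_phantom(
        length_um=20.0, width_um=6.0, center_thickness_nm=430.0,
        theta_deg=10.0, pixel_size_um=0.1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
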