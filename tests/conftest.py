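import pytest

from bonescrew import (
    RigSpec,
    ScrewGeometry,
    derive_insertion_coefficients,
    derive_stripping_coefficients,
)


@pytest.fixture(scope="session")
def hb65():
    """Reference HB 6.5 screw / 3.2 mm hole geometry."""
    return ScrewGeometry.hb65()


@pytest.fixture(scope="session")
def ins_coeffs(hb65):
    return derive_insertion_coefficients(hb65)


@pytest.fixture(scope="session")
def strip_coeffs(hb65):
    return derive_stripping_coefficients(hb65)


@pytest.fixture(scope="session")
def noise_free_rig():
    """Rig with all sensor effects disabled."""
    return RigSpec(torque_noise_sd=0.0, encoder_resolution=0.0,
                   drawwire_resolution=0.0)
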