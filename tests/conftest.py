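import numpy as np
import pytest

from jlphase import (
    CalibrationCurve,
    OPDMap,
    PolyLUT,
    build_lut,
    fiber_opd_map,
    fit_poly_lut,
    render_rgb,
)
from jlphase.phantoms import FiberSpec


@pytest.fixture(scope="session")
def fiber_spec():
    return FiberSpec()


@pytest.fixture(scope="session")
def fiber_reference(fiber_spec):
    """Reference fiber OPD map and its noise-free rendering at 0.2 µm/px."""
    opd = fiber_opd_map(fiber_spec, (256, 256), pixel_size=0.2)
    return opd, render_rgb(opd)


@pytest.fixture(scope="session")
def fiber_curve(fiber_spec, fiber_reference) -> CalibrationCurve:
    opd, image = fiber_reference
    return build_lut(image, opd, n_bins=50, opd_range=(0.0, fiber_spec.max_opd))


@pytest.fixture(scope="session")
def fiber_lut(fiber_curve) -> PolyLUT:
    return fit_poly_lut(fiber_curve, order=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
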