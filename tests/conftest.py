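import numpy as np
import pytest

from coroflow.flow_solver import FluidProperties
from coroflow.geometry import StenosisSpec, make_stenosed_phantom


@pytest.fixture
def fluid():
    return FluidProperties()


@pytest.fixture
def straight_tube():
    """r = 1.5 mm, L = 30 mm reference tube (zero-severity phantom)."""
    spec = StenosisSpec(r0_mm=1.5, length_mm=30.0, centre_mm=15.0,
                        stenosis_length_mm=10.0, severity_pct=0.0)
    return make_stenosed_phantom(spec, 129)


@pytest.fixture
def phantom60():
    """60% diameter stenosis in a 1.5 mm vessel."""
    spec = StenosisSpec(r0_mm=1.5, length_mm=30.0, centre_mm=15.0,
                        stenosis_length_mm=10.0, severity_pct=60.0)
    return make_stenosed_phantom(spec, 129)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def poiseuille_q_ml_min(dp_mmhg, r_mm, length_mm, mu=0.0035):
    """Closed-form Poiseuille flow, ml/min."""
    dp = dp_mmhg * 133.322
    r = r_mm * 1e-3
    length = length_mm * 1e-3
    q_si = np.pi * dp * r ** 4 / (8.0 * mu * length)
    return q_si / (1e-6 / 60.0)
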