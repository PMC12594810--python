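import numpy as np
import pytest

from rheojet import FlowCurve, SynthConfig, load_reference_table


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture
def exact_curve():
    """Noise-free power-law curve eta = 1000 * gamma^-1 on a log grid."""
    gamma = np.geomspace(0.3, 300.0, 20)
    return FlowCurve(
        sample_id="exact", replicate_id=0, shear_rate=gamma, viscosity=1000.0 / gamma
    )


@pytest.fixture
def quiet_cfg():
    return SynthConfig(seed=42, noise_cv=0.0)
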