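"""Shared fixtures: small geometries, sensor arrays and simulated sessions.

Everything is generated programmatically at session scope so expensive
objects (lead fields, simulated sessions) are built once per run.
"""

import numpy as np
import pytest

from laminarmeg.forward import build_lead_field
from laminarmeg.pipeline import default_session_config, fit_session
from laminarmeg.synthetic import (
    make_sensor_array,
    make_two_layer_model,
    simulate_session,
)


@pytest.fixture(scope="session")
def concentric_model():
    """Plain concentric icospheres (no wrinkle): analytic geometry."""
    return make_two_layer_model(radius=0.07, thickness=0.003, subdivisions=2)


@pytest.fixture(scope="session")
def wrinkled_model():
    """Wrinkled two-layer model: sources are visible to MEG."""
    return make_two_layer_model(
        radius=0.07, thickness=0.003, subdivisions=2, wrinkle_amplitude=0.007
    )


@pytest.fixture(scope="session")
def sensors_small():
    return make_sensor_array(n=60, helmet_radius=0.105)


@pytest.fixture(scope="session")
def leadfield_small(wrinkled_model, sensors_small):
    return build_lead_field(wrinkled_model, sensors_small)


@pytest.fixture(scope="session")
def small_session():
    """One simulated participant at test scale (162 pairs, 80 channels)."""
    cfg = default_session_config(
        seed=1, snr_db=0.0, subdivisions=2, n_sensors=80, trials_per_block=120
    )
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def small_fitted(small_session):
    return fit_session(small_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
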