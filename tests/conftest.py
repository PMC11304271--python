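import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 types x 3 batches x 8 cells at 32 px — enough for wiring tests."""
    from cytomad.synthetic import default_sim_config, generate_dataset

    return generate_dataset(default_sim_config(8, 32, seed=99))


@pytest.fixture(scope="session")
def disk_pair():
    """A noiseless circular cell: radius 10 px, peak phase 0.8."""
    from cytomad.synthetic import CellParams, render_cell

    params = CellParams(
        "disk", radius_px=10.0, eccentricity=0.0, orientation_rad=0.0,
        peak_phase=0.8, texture_granularity=2.0, texture_amplitude=0.0,
    )
    return render_cell(params, 32, np.random.default_rng(0))
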