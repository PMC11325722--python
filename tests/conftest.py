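import pytest

import oriens as o


@pytest.fixture(scope="session")
def basis():
    return o.ChannelBasis()


@pytest.fixture(scope="session")
def small_model():
    return o.make_forward_model(10, seed=11)


@pytest.fixture(scope="session")
def small_cfg():
    """Compact, high-SNR study conditions for fast unit tests."""
    return o.SimulationConfig(
        trials_per_orientation=20,
        trials_per_set=10,
        trials_per_set_2b=10,
        sampling_rate_hz=250,
        epoch_window_ms=(-400.0, 1000.0),
        noise_sd=0.5,
        signal_gain=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def exp1_small(small_cfg, small_model):
    return o.simulate_exp1(small_cfg, small_model)


@pytest.fixture(scope="session")
def exp2a_small(small_cfg, small_model):
    return o.simulate_exp2a(small_cfg, small_model, [0.0])


@pytest.fixture(scope="session")
def coarse_windows():
    """Four non-overlapping windows spanning the analysis range."""
    return o.WindowSpec(width_ms=100.0, step_ms=300.0, range_ms=(-300.0, 900.0))
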