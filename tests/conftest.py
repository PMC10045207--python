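import numpy as np
import pytest

from aerorate.synthetic import (
    SceneConfig,
    frame_times,
    simulate_flight_logs,
    simulate_roi_signals,
    _matched_logs,
)


@pytest.fixture(scope="session")
def calm_scene():
    """Default calm-hover scene, 20 s at 15 fps, 70 bpm."""
    return SceneConfig(seed=11)


@pytest.fixture(scope="session")
def calm_signals(calm_scene):
    """Signal-level simulation of the calm scene plus frame-matched logs."""
    signals, gt = simulate_roi_signals(calm_scene)
    gimbal, flight = simulate_flight_logs(calm_scene)
    fm_g, fm_f = _matched_logs(calm_scene, gimbal, flight, frame_times(calm_scene))
    return signals, gt, fm_f, fm_g


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
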