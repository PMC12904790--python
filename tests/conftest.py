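import numpy as np
import pytest

from gluim import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_movie():
    """Small rendered movie with 5 well-separated sites and ground truth."""
    cfg = sg.SimConfig(
        frame_rate=100.0,
        duration=30.0,
        image_shape=(48, 48),
        n_sites=5,
        footprint_sigma=1.5,
        baseline_photon_rate=20.0,
        site_brightness=80.0,
        rng_seed=5,
    )
    kin = sg.KineticParams(amplitude=1.5, tau_rise=0.002, tau_decay=0.05)
    centers = np.array([[10, 10], [10, 36], [24, 24], [38, 10], [38, 38]], float)
    r = np.random.default_rng(11)
    trains = [sg.simulate_release_train(0.3, 30.0, seed=r, site_id=i) for i in range(5)]
    return sg.render_movie(cfg, trains, kin, centers=centers)


@pytest.fixture(scope="session")
def tuned_session():
    """Tuned 3-site session (2 tuned, 1 flat) with stimulus log."""
    cfg = sg.SimConfig(
        frame_rate=20.0,
        duration=1.0,
        image_shape=(24, 24),
        n_sites=3,
        footprint_sigma=1.2,
        baseline_photon_rate=30.0,
        site_brightness=120.0,
        rng_seed=3,
    )
    tun = sg.make_tuning(3, kappa=[3.0, 3.0, 0.0], rate_max=3.0, rate_base=0.2, seed=1)
    kin = sg.KineticParams(amplitude=1.0, tau_rise=0.003, tau_decay=0.1)
    centers = np.array([[6, 6], [6, 18], [17, 12]], float)
    movie, log = sg.simulate_tuned_session(cfg, tun, kin, trials_per_direction=10, centers=centers)
    return movie, log
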