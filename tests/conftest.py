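import numpy as np
import pytest

import homingchains as hc


@pytest.fixture(scope="session")
def cfg():
    return hc.SyntheticConfig(seed=3)


@pytest.fixture(scope="session")
def geom(cfg):
    return hc.site_geometry(cfg)


@pytest.fixture(scope="session")
def population(cfg):
    """Nine calibrated synthetic birds; shared across the suite."""
    return hc.generate_population(cfg, 9)


@pytest.fixture()
def straight_beeline(cfg):
    """Perfectly straight release-to-home flight at 1 Hz."""
    n_seg = int(cfg.beeline_m / cfg.speed_mps)
    t = np.arange(n_seg + 1, dtype=float)
    y = cfg.beeline_m - cfg.speed_mps * t
    return hc.Trajectory(t, np.zeros_like(t), y)


@pytest.fixture()
def zigzag():
    """Small asymmetric fixture polyline for elementwise oracles."""
    t = np.arange(7, dtype=float)
    x = np.array([0.0, 3.0, -1.0, 4.0, 2.0, 6.0, 5.0])
    y = np.array([0.0, 2.0, 5.0, 7.0, 11.0, 13.0, 17.0])
    return hc.Trajectory(t, x, y)
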