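import numpy as np
import pytest

import spikedff as sdf


@pytest.fixture(scope="session")
def cfg():
    """Desk-scale 64x64 fixture optics."""
    return sdf.fixture_optics()


@pytest.fixture(scope="session")
def sweep():
    """Default 5 ms power-linear focal sweep."""
    return sdf.default_sweep()


@pytest.fixture(scope="session")
def sphere_scene(cfg):
    return sdf.make_fixture("sphere", seed=0, cfg=cfg)


@pytest.fixture(scope="session")
def sphere_stream(cfg, sweep, sphere_scene):
    """One simulated sweep over the uniform disc (shared, read-only)."""
    return sdf.generate_events(sphere_scene, sweep, cfg)


@pytest.fixture(scope="session")
def multi_scene(cfg):
    return sdf.make_fixture("multi_depth", seed=1, cfg=cfg)


@pytest.fixture(scope="session")
def multi_stream(cfg, sweep, multi_scene):
    return sdf.generate_events(multi_scene, sweep, cfg)


def _single_pixel_stream(times_us, polarities, sensor=(4, 4), x=1, y=2):
    times_us = np.asarray(times_us, dtype=np.int64)
    n = len(times_us)
    return sdf.EventStream(times_us, np.full(n, x), np.full(n, y),
                           np.asarray(polarities, dtype=np.int8),
                           sensor_shape=sensor)


@pytest.fixture
def pixel_stream():
    """Factory building an EventStream that stimulates a single pixel."""
    return _single_pixel_stream
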