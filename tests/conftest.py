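import numpy as np
import pytest

from kymodiff import AcquisitionMeta, Track


@pytest.fixture(scope="session")
def meta() -> AcquisitionMeta:
    return AcquisitionMeta()


def brownian_positions(rng, n, D, dt, noise_sd=0.0, x0=5.0):
    """Reference Brownian path: cumulative N(0, 2 D dt) increments + noise."""
    x = x0 + np.cumsum(rng.normal(0.0, np.sqrt(2.0 * D * dt), n))
    if noise_sd:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


def make_track(positions, meta, track_id="t", channel="green", visible=None):
    return Track(track_id, channel,
                 np.arange(len(positions), dtype=np.int64),
                 np.asarray(positions, float), meta, visible)
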