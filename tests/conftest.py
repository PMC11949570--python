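import numpy as np
import pytest

from pxarsim import PointCommunity


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def make_rng():
    """Factory for independent seeded generators inside multi-seed loops."""

    def _make(seed):
        return np.random.default_rng(np.random.SeedSequence([20260920, int(seed)]))

    return _make


@pytest.fixture
def toy_community():
    """Three points, two species; the individual of species 1 at (0.7, 0.7)
    dies, everything else survives.  Small enough to enumerate by hand."""
    return PointCommunity(
        x=np.array([0.2, 0.7, 0.2]),
        y=np.array([0.2, 0.7, 0.7]),
        species=np.array([1, 1, 2]),
        alive_t2=np.array([True, False, True]),
    )
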