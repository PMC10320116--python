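import numpy as np
import pytest

from volseg import fixtures as fx


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_spec():
    return fx.FixtureSpec(dims=(16, 16, 16), n_blobs=2, n_segments=2, seed=11)


@pytest.fixture()
def small_grid(small_spec):
    return fx.make_blob_volume(small_spec)


@pytest.fixture()
def entry_spec():
    """The standard end-to-end fixture: 64^3 volume, 3 spheres, 1 icosphere."""
    return fx.FixtureSpec(dims=(64, 64, 64), n_blobs=4, n_segments=3, seed=7)
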