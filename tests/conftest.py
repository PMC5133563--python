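import numpy as np
import pytest

import malsite as ms


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal benchmark shared across tests (60+240 windows)."""
    spec = ms.SyntheticSpec(n_positive=60, n_negative=240, seed=11)
    ds = ms.generate_windows(spec)
    X = ms.encode_matrix(ds.windows)
    y = np.array([w.label for w in ds.windows], dtype=int)
    return ds, X, y


@pytest.fixture(scope="session")
def property_table():
    return ms.default_property_table()


@pytest.fixture
def fast_factory():
    """A cheap pipeline (15 mRMR features) for CV protocol tests."""

    def factory(seed: int) -> ms.Pipeline:
        return ms.Pipeline(mrmr=ms.MRMRConfig(n_features=15), seed=seed)

    return factory
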