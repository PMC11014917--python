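import numpy as np
import pytest

import spindlesim as ss


@pytest.fixture(scope="session")
def small_params():
    """A reduced system that still exercises every mechanism: fewer pairs,
    fewer MTs, shorter run."""
    return ss.preset("control").replace(n_ch=12, n_mt_per_pole=80,
                                        t_end=180.0)


@pytest.fixture(scope="session")
def small_run(small_params):
    """One completed small replicate (shared across read-only tests)."""
    return ss.run_replicate(small_params, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
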