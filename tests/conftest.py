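import numpy as np
import pytest

from myograde import io as mio
from myograde import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording(rng):
    """A 1 s random 4-channel recording with a grade label."""
    return mio.Recording(subject_id="s01", channels=rng.normal(size=(4, 1000)),
                         coarse_grade=3)


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (600 activity segments), built once."""
    ds = synthetic.generate_benchmark(seed=0)
    return ds, synthetic.benchmark_segments(ds)
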