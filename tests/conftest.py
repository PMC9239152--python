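import numpy as np
import pytest

from multihic.genome_model import RepliconSpec, build_layout, default_layout


@pytest.fixture(scope="session")
def c58_layout():
    return default_layout()


@pytest.fixture()
def mini_layout():
    """Two small replicons, no rotation: 10 + 5 bins of 10 kb."""
    reps = [
        RepliconSpec("chrA", 100_000, "circular", origin_pos=50_000),
        RepliconSpec("chrB", 50_000, "linear", origin_pos=25_000),
    ]
    return build_layout(reps, bin_size=10_000, ch1_start_offset=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
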