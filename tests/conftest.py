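import numpy as np
import pytest

import forkdose as fd


@pytest.fixture
def genome_map():
    """Default circular genome: oriC at 0 deg, terC at 172 deg."""
    return fd.GenomeMap()


@pytest.fixture
def right_arm_probes():
    """2000 probes at 1 kb spacing spanning 2 Mbp of the right replichore."""
    return (np.arange(2000) * 1000 + 500).astype(np.int64)


@pytest.fixture
def random_profile(right_arm_probes):
    rng = np.random.default_rng(42)
    return fd.DosageProfile(
        right_arm_probes, rng.normal(0.0, 0.3, right_arm_probes.size)
    )
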