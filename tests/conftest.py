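import numpy as np
import pytest

import cadekit as ck


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-sample synthetic cohort shared by read-only tests."""
    spec = ck.CohortSpec(
        groups=(("G1", "benign", 14), ("G5", "Tub_mod", 10), ("G5", "Sig", 6)),
        image_size=(64, 64),
        seed=99,
    )
    return ck.generate_cohort(spec)
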