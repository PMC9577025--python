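import numpy as np
import pytest

from zerolink import AbundanceProfile


@pytest.fixture
def toy_profile() -> AbundanceProfile:
    """4 taxa x 5 samples with a planted zero pattern."""
    values = np.array(
        [
            [5, 0, 3, 1, 2],
            [0, 0, 4, 2, 1],
            [1, 2, 0, 0, 3],
            [2, 1, 1, 1, 1],
        ],
        dtype=float,
    )
    return AbundanceProfile(
        ["taxA", "taxB", "taxC", "taxD"],
        ["s1", "s2", "s3", "s4", "s5"],
        values,
        {"state": "counts"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
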