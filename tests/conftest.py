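import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_unit_quaternion(rng, n=None):
    q = rng.standard_normal(4 if n is None else (n, 4))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
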