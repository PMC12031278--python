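import numpy as np
import pytest

from skiturn import quat


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def assert_same_rotation(q1, q2, tol=1e-9):
    """Compare rotations, not components (q and -q are the same rotation)."""
    ang = quat.rotation_angle_between(q1, q2)
    assert ang < tol, f"rotations differ by {ang} rad"
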