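import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dscmf import AssociationMatrix, gip_kernel


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_association(rng, n_l=12, n_d=10, density=0.3):
    """Random binary association matrix where every row/column is reachable."""
    while True:
        values = (rng.random((n_l, n_d)) < density).astype(float)
        if values.sum() > 0:
            return AssociationMatrix(
                [f"l{i:02d}" for i in range(n_l)],
                [f"d{j:02d}" for j in range(n_d)],
                values,
            )


@pytest.fixture
def small_assoc(rng):
    return random_association(rng)


@pytest.fixture
def small_kernels(small_assoc):
    return (
        gip_kernel(small_assoc, "lncrna"),
        gip_kernel(small_assoc, "disease"),
    )
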