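import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg", force=True)

from admixalign import MembershipMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_q(rng):
    """Factory for random row-stochastic membership matrices."""

    def make(n: int, k: int, run_id: str = "") -> MembershipMatrix:
        return MembershipMatrix.from_array(
            rng.dirichlet(np.ones(k), size=n), run_id=run_id
        )

    return make
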