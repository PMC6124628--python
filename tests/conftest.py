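import numpy as np
import pytest

from hpmr import SummarizedData, make_fixture


@pytest.fixture
def tiny_data():
    """Three hand-specified variants with exact ratio estimates 0.4, 0.4, 0.8."""
    return SummarizedData(
        variant_ids=("a", "b", "c"),
        beta_x=np.array([0.5, 0.25, 0.5]),
        beta_y=np.array([0.2, 0.1, 0.4]),
        se_y=np.array([0.05, 0.05, 0.05]),
    )


@pytest.fixture
def valid_fixture():
    """Ten variants, all valid, theta = 0.2."""
    return make_fixture(10, 0.2, seed=42)


def random_summarized(rng, J, theta_scale=0.3, heterogeneous=True):
    """Random well-scaled summary dataset for oracle comparisons."""
    beta_x = rng.uniform(0.2, 0.8, J) * rng.choice([-1.0, 1.0], J)
    theta = rng.normal(0.0, theta_scale, J if heterogeneous else 1)
    beta_y = theta * beta_x
    se_y = rng.uniform(0.02, 0.15, J)
    return SummarizedData(
        variant_ids=tuple(f"v{j}" for j in range(J)),
        beta_x=beta_x,
        beta_y=beta_y + rng.normal(0, se_y),
        se_y=se_y,
    )
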