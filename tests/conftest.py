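import numpy as np
import pytest

from crtlmm import DesignConfig, NullDataset, generate_null_dataset


@pytest.fixture
def hand_dataset() -> NullDataset:
    """8-observation fixture with known ANOVA decomposition.

    Clusters (1,1,2,2,3,3,4,4), arms (0,0,0,0,1,1,1,1), outcomes chosen so
    that every cluster has within-variance 2 about its mean, cluster means
    are (1,3,2,4) and arm means (2,3): MSW = 2, MSB = 4, beta1_hat = 1.
    """
    data = NullDataset(
        y=np.array([0.0, 2.0, 2.0, 4.0, 1.0, 3.0, 3.0, 5.0]),
        cluster=np.repeat([1, 2, 3, 4], 2),
        arm=np.repeat([0, 0, 1, 1], 2),
    )
    data.validate()
    return data


def make_dataset(K=10, N=5, sigma_b2=0.5, sigma2=1.0, seed=0) -> NullDataset:
    return generate_null_dataset(DesignConfig(K=K, N=N, sigma_b2=sigma_b2, sigma2=sigma2, seed=seed))


@pytest.fixture
def random_fixtures():
    """100 small random balanced datasets spanning interior and boundary fits."""
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(100):
        K = int(rng.choice([4, 6, 8, 10]))
        N = int(rng.choice([2, 3, 5]))
        sb2 = float(rng.uniform(0.0, 2.0))
        s2 = float(rng.uniform(0.2, 3.0))
        cfg = DesignConfig(K=K, N=N, sigma_b2=sb2, sigma2=s2, seed=int(rng.integers(2**31)))
        out.append(generate_null_dataset(cfg))
    return out
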