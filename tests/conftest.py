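import numpy as np
import pytest

from ltranshgg.core import SampleMatrix, SubgroupParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cluster_data():
    """Two well-separated spherical clusters at +-5*1_p, p = 5, n = 200."""
    gen = np.random.default_rng(3)
    p, n = 5, 200
    X = np.vstack([gen.standard_normal((n // 2, p)) + 5.0,
                   gen.standard_normal((n // 2, p)) - 5.0])
    labels = np.repeat([0, 1], n // 2)
    return SampleMatrix(values=X), labels


def random_pd_precision(rng, p, cond=4.0):
    """A random symmetric PD precision with moderate conditioning."""
    Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    eigs = np.exp(rng.uniform(-np.log(cond) / 2, np.log(cond) / 2, p))
    return (Q * eigs) @ Q.T


@pytest.fixture
def standard_subgroup():
    return SubgroupParams(pi=1.0, mu=np.zeros(2), theta=np.eye(2))
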