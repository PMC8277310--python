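import numpy as np
import pytest

from nutrispace import load_defaults
from nutrispace.synthetic import CohortSpec, TrajectorySpec


@pytest.fixture(scope="session")
def cfg():
    return load_defaults()


@pytest.fixture(scope="session")
def healthy_spec(cfg):
    return CohortSpec.from_config(cfg, "healthy")


@pytest.fixture(scope="session")
def mets_spec(cfg):
    return CohortSpec.from_config(cfg, "mets")


@pytest.fixture(scope="session")
def intervention_spec(cfg):
    return CohortSpec.from_config(cfg, "intervention")


@pytest.fixture(scope="session")
def trajectory_spec(cfg):
    return TrajectorySpec.from_config(cfg)


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up: sort, scale by m/rank,
    enforce monotonicity from the largest down, cap at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def rra_oracle(ranks):
    """Independent rho oracle: every beta order-statistic probability via
    the binomial tail identity P(Beta(k, m-k+1) <= r) = P(Bin(m, r) >= k)."""
    from math import comb

    r = sorted(ranks)
    m = len(r)
    probs = []
    for k, rk in enumerate(r, start=1):
        tail = sum(comb(m, j) * rk**j * (1 - rk) ** (m - j) for j in range(k, m + 1))
        probs.append(tail)
    return min(probs)
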