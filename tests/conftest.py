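import numpy as np
import pandas as pd
import pytest

from dmrhmm.counts import COLUMNS, CpGTable
from dmrhmm.mixture import BetaMixture


def random_mixture(rng) -> BetaMixture:
    """A random valid constrained mixture for property tests."""
    w = rng.dirichlet([5.0, 5.0, 1.0])
    return BetaMixture(w_h=w[0], w_l=w[1], w_unif=w[2],
                       alpha_h=float(rng.uniform(1.0, 15.0)),
                       beta_l=float(rng.uniform(1.0, 15.0)))


def random_table(rng, n_sites=20, chrom="chr1", max_depth=12) -> CpGTable:
    pos = np.sort(rng.choice(np.arange(2, 5000, 2), size=n_sites, replace=False))
    n1 = rng.poisson(max_depth / 2, n_sites)
    n2 = rng.poisson(max_depth / 2, n_sites)
    m1 = rng.binomial(n1, rng.random(n_sites))
    m2 = rng.binomial(n2, rng.random(n_sites))
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "m1": m1, "u1": n1 - m1,
                       "m2": m2, "u2": n2 - m2})[list(COLUMNS)]
    return CpGTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return CpGTable.from_records([
        ("chr1", 100, 5, 0, 0, 5),
        ("chr1", 150, 3, 3, 3, 3),
        ("chr1", 200, 0, 8, 8, 0),
        ("chr2", 50, 2, 2, 4, 0),
    ])
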