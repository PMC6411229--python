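import warnings

import numpy as np
import pytest

from cophos.types import KSAnnotation, PhosphoProfileMatrix, PhosphoSite


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, site_names=None, states=None):
    """Build a profile matrix from a raw array, suppressing the few-states warning."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sites = [
        PhosphoSite.parse(name)
        for name in (site_names or [f"PROT{i}_S{i + 1}" for i in range(n)])
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return PhosphoProfileMatrix(
            sites=sites,
            states=states or [f"s{j}" for j in range(m)],
            values=values,
        )


@pytest.fixture
def toy_matrix(rng):
    """12 sites x 20 states: two 4-site correlated blocks plus 4 noise sites."""
    m = 20
    f1 = rng.standard_normal(m)
    f2 = rng.standard_normal(m)
    f2 -= f1 * (f1 @ f2) / (f1 @ f1)  # orthogonal kinase programs
    rows = []
    for factor in (f1, f1, f1, f1, f2, f2, f2, f2):
        rows.append(factor + 0.3 * rng.standard_normal(m))
    for _ in range(4):
        rows.append(rng.standard_normal(m))
    return make_matrix(np.array(rows))


@pytest.fixture
def toy_ksa(toy_matrix):
    """K1 annotates the first block, K2 the second."""
    s = toy_matrix.sites
    return KSAnnotation.from_pairs(
        [("K1", s[0]), ("K1", s[1]), ("K1", s[2]), ("K1", s[3]),
         ("K2", s[4]), ("K2", s[5]), ("K2", s[6]), ("K2", s[7])]
    )
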