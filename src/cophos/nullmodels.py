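"""Permutation null models for co-phosphorylation distributions.

Three randomization schemes destroy the site-pair correlation structure
while conserving value multisets at different granularities:

- ``within_state``: permute intensities across sites separately inside each
  state column (each state's marginal distribution is preserved);
- ``within_site``: permute each site's profile across states (each site's
  marginal distribution is preserved);
- ``global``: permute all entries of the matrix jointly.

Comparing the observed co-phosphorylation distribution against the pooled
null distribution (two-sample Kolmogorov-Smirnov test) assesses whether the
data carry more strongly correlated site pairs than chance predicts; the
observed distribution is typically wider than any of the three nulls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import build_cophos_network
from .types import PhosphoProfileMatrix

PERMUTATION_SCHEMES = ("within_state", "within_site", "global")

SeedLike = int | np.random.SeedSequence | np.random.Generator


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permute_matrix(
    matrix: PhosphoProfileMatrix, scheme: str, seed: SeedLike
) -> PhosphoProfileMatrix:
    """Return a permuted copy of the matrix under the given scheme.

    Shape and labels are unchanged; the value multiset is conserved at the
    scheme's granularity (per column / per row / globally). Deterministic
    for a fixed integer seed.
    """
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(
            f"unknown permutation scheme {scheme!r}; "
            f"expected one of {PERMUTATION_SCHEMES}"
        )
    rng = _rng(seed)
    values = matrix.values.copy()
    if scheme == "within_state":
        for j in range(values.shape[1]):
            values[:, j] = rng.permutation(values[:, j])
    elif scheme == "within_site":
        for i in range(values.shape[0]):
            values[i, :] = rng.permutation(values[i, :])
    else:  # global
        flat = rng.permutation(values.ravel())
        values = flat.reshape(values.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return PhosphoProfileMatrix(
            sites=list(matrix.sites), states=list(matrix.states), values=values
        )


def null_cophos_distribution(
    matrix: PhosphoProfileMatrix,
    scheme: str,
    method: str = "bicor",
    n_perm: int = 100,
    seed: SeedLike = 0,
) -> np.ndarray:
    """Pooled co-phosphorylation values over ``n_perm`` permuted replicates.

    A single seed spawns one independent substream per replicate (numpy
    SeedSequence spawning), so the pooled distribution is reproducible and
    independent of evaluation order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_perm)
    pooled: list[np.ndarray] = []
    for child in children:
        permuted = permute_matrix(matrix, scheme, np.random.default_rng(child))
        network = build_cophos_network(permuted, method=method)
        pooled.append(network.condensed())
    return np.concatenate(pooled)


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison.

    Returns (D, p) with D = sup |ECDF_a - ECDF_b|; the p-value uses the
    asymptotic two-sample distribution, with scipy's exact computation for
    small samples.
    """
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.ks_2samp(sample_a, sample_b, method="auto")
    return float(result.statistic), float(result.pvalue)


def dimension_adequacy(
    matrix: PhosphoProfileMatrix,
    dims: list[int],
    n_rep: int = 100,
    n_perm: int = 10,
    seed: SeedLike = 0,
) -> pd.DataFrame:
    """Effect of the number of biological states on the co-phosphorylation signal.

    For each d in ``dims``, subsample d state columns ``n_rep`` times;
    report (averaged over replicates) the sd of the observed
    co-phosphorylation distribution, the sd of its global-permutation null,
    and the KS statistic between the two. As d grows the null narrows
    (roughly like 1/sqrt(d-1)) while planted correlation structure becomes
    easier to distinguish from it (increasing D).
    """
    m = matrix.n_states
    for d in dims:
        if not 3 <= d <= m:
            raise ValueError(f"dimension {d} out of range [3, {m}]")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for d in dims:
        sds_orig, sds_null, ks_ds = [], [], []
        # one substream family per dimension so adding dims never reshuffles
        children = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(d,)
        ).spawn(n_rep)
        for child in children:
            rng = np.random.default_rng(child)
            cols = rng.choice(m, size=d, replace=False)
            sub = matrix.subset_states(sorted(cols))
            observed = build_cophos_network(sub).condensed()
            null = null_cophos_distribution(
                sub, "global", n_perm=n_perm, seed=child.spawn(1)[0]
            )
            sds_orig.append(np.std(observed, ddof=1))
            sds_null.append(np.std(null, ddof=1))
            ks_ds.append(ks_compare(observed, null)[0])
        rows.append(
            {
                "d": d,
                "sd_original": float(np.mean(sds_orig)),
                "sd_null": float(np.mean(sds_null)),
                "ks_D": float(np.mean(ks_ds)),
            }
        )
    return pd.DataFrame(rows)
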