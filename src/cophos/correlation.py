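"""Co-phosphorylation: robust correlation between phosphorylation profiles.

Co-phosphorylation of two phosphosites is the correlation between their
phosphorylation profiles across biological states. The primary estimator is
the biweight midcorrelation (bicor), which standardizes observations by the
median and median absolute deviation and downweights outlying states with
Tukey biweights, making it markedly more robust to single aberrant samples
than the product-moment (Pearson) correlation. The complete weighted graph
over all measured sites with edge weight c_pq is the co-phosphorylation
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import stats

from .types import PhosphoProfileMatrix, PhosphoSite

logger = logging.getLogger(__name__)

#: Tukey biweight tuning constant: deviations beyond BIWEIGHT_SCALE * mad
#: receive zero weight.
BIWEIGHT_SCALE = 9.0


class DegenerateProfileError(ValueError):
    """A profile has zero spread (mad or variance 0) and cannot be correlated.

    ``index`` identifies the offending vector (0 for x, 1 for y) when the
    error arises from a pairwise call.
    """

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation (no consistency factor)."""
    return float(np.median(np.abs(x - np.median(x))))


def _bicor_weighted_deviation(x: np.ndarray) -> np.ndarray:
    """Unnormalized biweight form (x_i - med(x)) w_i of a profile, with
    w_i = (1 - u_i^2)^2 I(1 - |u_i|), u_i = (x_i - med(x)) / (9 mad(x))."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = _mad(x)
    if mad == 0.0:
        raise DegenerateProfileError("profile has zero median absolute deviation")
    dev = x - med
    u = dev / (BIWEIGHT_SCALE * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return dev * w


def _bicor_standardize(x: np.ndarray) -> np.ndarray:
    """Biweight-standardized profile x'_i = (x_i - med(x)) w_i / sqrt(sum_j [...]^2).

    Bicor of two profiles is the dot product of their standardized forms.
    """
    v = _bicor_weighted_deviation(x)
    norm = np.sqrt(np.sum(v**2))
    if norm == 0.0:
        raise DegenerateProfileError("all observations received zero weight")
    return v / norm


def biweight_midcorrelation(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two profiles, clamped to [-1, 1].

    Requires length >= 3 and nonzero median absolute deviation in both
    vectors; raises :class:`DegenerateProfileError` (with ``index`` 0 or 1)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    try:
        vx = _bicor_weighted_deviation(x)
    except DegenerateProfileError as err:
        raise DegenerateProfileError(str(err), index=0) from None
    try:
        vy = _bicor_weighted_deviation(y)
    except DegenerateProfileError as err:
        raise DegenerateProfileError(str(err), index=1) from None
    # all three products go through np.dot so that for x == y the numerator
    # and both norms are the same float, and sqrt(s * s) == s in IEEE
    # arithmetic makes self-correlation exactly 1
    sx, sy = float(np.dot(vx, vx)), float(np.dot(vy, vy))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateProfileError(
            "all observations received zero weight", index=0 if sx == 0 else 1
        )
    c = float(np.dot(vx, vy) / np.sqrt(sx * sy))
    return min(1.0, max(-1.0, c))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two profiles, clamped to [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    xc = x - np.mean(x)
    yc = y - np.mean(y)
    sx, sy = float(np.dot(xc, xc)), float(np.dot(yc, yc))
    if sx == 0.0:
        raise DegenerateProfileError("profile has zero variance", index=0)
    if sy == 0.0:
        raise DegenerateProfileError("profile has zero variance", index=1)
    r = float(np.dot(xc, yc) / np.sqrt(sx * sy))
    return min(1.0, max(-1.0, r))


def _pearson_standardize(x: np.ndarray) -> np.ndarray:
    xc = np.asarray(x, dtype=float) - np.mean(x)
    norm = np.sqrt(np.sum(xc**2))
    if norm == 0.0:
        raise DegenerateProfileError("profile has zero variance")
    return xc / norm


_STANDARDIZERS = {
    "bicor": _bicor_standardize,
    "pearson": _pearson_standardize,
}


@dataclass
class CoPhosNetwork:
    """Complete weighted graph over measured phosphosites.

    ``weights[i, j]`` is the co-phosphorylation c_pq of sites i and j;
    the matrix is symmetric with unit diagonal and entries in [-1, 1].
    Profiles with zero spread are excluded at construction and listed in
    ``excluded``.
    """

    sites: list[PhosphoSite]
    weights: np.ndarray
    method: str = "bicor"
    excluded: list[PhosphoSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sites)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over the site list")

    @cached_property
    def site_index(self) -> dict[PhosphoSite, int]:
        return {s: i for i, s in enumerate(self.sites)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def weight(self, p: PhosphoSite, q: PhosphoSite) -> float:
        return float(self.weights[self.site_index[p], self.site_index[q]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle weights (i < j), the all-pair distribution A."""
        iu = np.triu_indices(self.n_sites, k=1)
        return self.weights[iu]

    def __contains__(self, site: PhosphoSite) -> bool:
        return site in self.site_index


def build_cophos_network(
    matrix: PhosphoProfileMatrix,
    method: str = "bicor",
    block_size: int | None = None,
) -> CoPhosNetwork:
    """Build the co-phosphorylation network over all site pairs.

    Each profile is standardized once (so all-pair correlation reduces to a
    matrix product), computed blockwise over ``block_size`` rows to bound
    memory; results are independent of the block size. Degenerate profiles
    (zero mad for bicor, zero variance for pearson) are excluded from the
    network and logged rather than silently given weights.
    """
    if method not in _STANDARDIZERS:
        raise ValueError(f"unknown correlation method {method!r}")
    standardize = _STANDARDIZERS[method]

    kept_sites: list[PhosphoSite] = []
    excluded: list[PhosphoSite] = []
    rows: list[np.ndarray] = []
    for site, profile in zip(matrix.sites, matrix.values):
        try:
            rows.append(standardize(profile))
            kept_sites.append(site)
        except DegenerateProfileError:
            excluded.append(site)
    if excluded:
        logger.info(
            "excluded %d degenerate profiles from the network: %s",
            len(excluded),
            ", ".join(str(s) for s in excluded[:10])
            + ("..." if len(excluded) > 10 else ""),
        )
    if not kept_sites:
        raise ValueError("no non-degenerate profiles; cannot build a network")

    standardized = np.vstack(rows)
    n = standardized.shape[0]
    weights = np.empty((n, n), dtype=float)
    step = n if block_size is None else max(1, int(block_size))
    for start in range(0, n, step):
        stop = min(start + step, n)
        weights[start:stop] = standardized[start:stop] @ standardized.T
    np.clip(weights, -1.0, 1.0, out=weights)
    np.fill_diagonal(weights, 1.0)
    return CoPhosNetwork(
        sites=kept_sites, weights=weights, method=method, excluded=excluded
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Moment summary of a co-phosphorylation distribution.

    Kurtosis is reported non-excess (a normal distribution gives 3).
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n_pairs: int


def summarize_distribution(values: np.ndarray) -> DistributionSummary:
    """Sample mean, sd (ddof=1) and standardized third/fourth moments."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to summarize")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("constant sample: skewness and kurtosis undefined")
    return DistributionSummary(
        mean=float(np.mean(values)),
        sd=sd,
        skewness=float(stats.skew(values)),
        kurtosis=float(stats.kurtosis(values, fisher=False)),
        n_pairs=int(values.size),
    )
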