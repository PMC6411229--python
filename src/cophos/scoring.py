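"""Naive Bayes kinase-substrate scoring on the co-phosphorylation network.

Two phosphosites annotated as substrates of the same kinase form a
*shared-kinase pair*; empirically their co-phosphorylation distribution S is
shifted to the right of the background distribution A over all site pairs.
The score of kinase k for site p accumulates, over p's annotated neighbours
q in T_k, the log-likelihood ratio of observing co-phosphorylation at least
as high as c_pq under S versus under A:

    h(k, p) = sum_{q in (P intersect T_k), q != p}
              log2( Pr(C > c_pq | S) / Pr(C > c_pq | A) )

Kinases are ranked per site in decreasing h. The tail probabilities are
empirical survival functions with an add-one continuity correction, so the
ratio is finite over the whole support.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .correlation import CoPhosNetwork
from .types import KSAnnotation, PhosphoSite, PredictionTable

logger = logging.getLogger(__name__)

#: Sentinel for a (kinase, site) pair with no annotated neighbour measured in
#: the data: absence of evidence, distinct from a likelihood ratio of 0.
UNSCORABLE = None


def collect_shared_kinase_values(
    network: CoPhosNetwork, ksa: KSAnnotation
) -> np.ndarray:
    """Co-phosphorylation values of all shared-kinase pairs (distribution S).

    Every unordered pair of distinct network sites sharing at least one
    annotated kinase contributes exactly one value, regardless of how many
    kinases it shares.
    """
    pairs: set[tuple[int, int]] = set()
    for kinase in ksa.kinases:
        indices = sorted(
            network.site_index[s]
            for s in ksa.substrates(kinase)
            if s in network
        )
        pairs.update(itertools.combinations(indices, 2))
    if not pairs:
        raise ValueError(
            "no shared-kinase pair is measured in the network; "
            "cannot fit the shared-kinase tail model"
        )
    idx = np.array(sorted(pairs))
    return network.weights[idx[:, 0], idx[:, 1]]


def _survival(sorted_values: np.ndarray, c: np.ndarray, eps: float) -> np.ndarray:
    """Add-one empirical survival (#{v > c} + 1) / (n + 1), clamped to [eps, 1]."""
    n = sorted_values.size
    greater = n - np.searchsorted(sorted_values, c, side="right")
    return np.clip((greater + 1) / (n + 1), eps, 1.0)


@dataclass(frozen=True)
class TailModel:
    """Empirical survival estimators for the background (A) and shared-kinase
    (S) co-phosphorylation distributions.

    Both estimators are monotone non-increasing in c and clamped to
    [epsilon, 1]; the add-one correction keeps them strictly positive above
    the support, so log-likelihood ratios never degenerate.
    """

    background_sorted: np.ndarray
    shared_sorted: np.ndarray
    eps_background: float
    eps_shared: float

    def survival_background(self, c) -> np.ndarray:
        return _survival(self.background_sorted, np.asarray(c, float), self.eps_background)

    def survival_shared(self, c) -> np.ndarray:
        return _survival(self.shared_sorted, np.asarray(c, float), self.eps_shared)

    def log_likelihood_ratio(self, c) -> np.ndarray:
        """log2 of Pr(C > c | S) / Pr(C > c | A), elementwise.

        The logarithm goes through math.log2 (libm) rather than numpy's
        SIMD loop, which can differ in the last ulp; this keeps scores
        bit-identical between vectorized and scalar code paths.
        """
        ratio = self.survival_shared(c) / self.survival_background(c)
        out = np.array([math.log2(v) for v in np.ravel(ratio)])
        return out.reshape(np.shape(ratio))


def fit_tail_model(
    all_values: np.ndarray,
    shared_values: np.ndarray,
    epsilon: float | None = None,
) -> TailModel:
    """Fit the background/shared tail models from observed pair weights.

    ``epsilon`` floors the survival probabilities; by default it is the
    natural floor of the add-one estimator, 1/(n+1) per distribution.
    """
    all_values = np.asarray(all_values, dtype=float)
    shared_values = np.asarray(shared_values, dtype=float)
    if all_values.size == 0 or shared_values.size == 0:
        raise ValueError("both samples must be non-empty to fit tail models")
    return TailModel(
        background_sorted=np.sort(all_values),
        shared_sorted=np.sort(shared_values),
        eps_background=epsilon if epsilon is not None else 1.0 / (all_values.size + 1),
        eps_shared=epsilon if epsilon is not None else 1.0 / (shared_values.size + 1),
    )


def fit_tail_model_from_network(
    network: CoPhosNetwork, ksa: KSAnnotation, epsilon: float | None = None
) -> TailModel:
    """Convenience: fit A from all network pairs and S from shared-kinase pairs."""
    return fit_tail_model(
        network.condensed(),
        collect_shared_kinase_values(network, ksa),
        epsilon=epsilon,
    )


def score_kinase_site(
    kinase: str,
    site: PhosphoSite,
    network: CoPhosNetwork,
    ksa: KSAnnotation,
    tails: TailModel,
) -> float | None:
    """Log-likelihood score h(kinase, site), or UNSCORABLE (None).

    Sums the tail log-likelihood ratio over the kinase's annotated
    substrates measured in the network, excluding the site itself. Returns
    the UNSCORABLE sentinel when no such neighbour exists (a score of 0
    would wrongly assert equal likelihood under S and A).
    """
    if site not in network:
        raise KeyError(f"site {site} is not in the network")
    p_idx = network.site_index[site]
    neighbour_idx = [
        network.site_index[q]
        for q in ksa.substrates(kinase)
        if q in network and q != site
    ]
    if not neighbour_idx:
        return UNSCORABLE
    weights = network.weights[p_idx, sorted(neighbour_idx)]
    # fsum: correctly rounded and order-independent, so scores are exactly
    # reproducible regardless of neighbour evaluation order
    return math.fsum(tails.log_likelihood_ratio(weights))


def rank_all(
    network: CoPhosNetwork, ksa: KSAnnotation, tails: TailModel
) -> PredictionTable:
    """Score every (kinase, site) pair and rank kinases per site.

    Vectorized over the whole network: the log-likelihood-ratio transform of
    the weight matrix is computed once, and each kinase's score column is a
    sum over its measured-substrate columns. Ties in the per-site descending
    sort break on ascending kinase name.
    """
    n = network.n_sites
    llr = tails.log_likelihood_ratio(network.weights)
    entries: dict[tuple[str, PhosphoSite], float] = {}
    n_scorable_kinases = 0
    for kinase in sorted(ksa.kinases):
        sub_idx = np.array(
            sorted(
                network.site_index[s]
                for s in ksa.substrates(kinase)
                if s in network
            ),
            dtype=int,
        )
        if sub_idx.size == 0:
            continue
        n_scorable_kinases += 1
        sub_cols = llr[:, sub_idx]
        # fsum per row: correctly rounded, hence independent of column order
        scores = np.fromiter(
            (math.fsum(row) for row in sub_cols), dtype=float, count=n
        )
        # a site that is itself a substrate must not count its self-edge
        member = np.zeros(n, dtype=bool)
        member[sub_idx] = True
        for i in sub_idx:
            scores[i] = math.fsum(llr[i, sub_idx[sub_idx != i]])
        counts = np.full(n, sub_idx.size)
        counts[member] -= 1
        for i, site in enumerate(network.sites):
            if counts[i] > 0:
                entries[(kinase, site)] = float(scores[i])
    if not entries:
        raise ValueError("no scorable (kinase, site) pair; check the annotation")
    table = PredictionTable.from_scores(entries)
    coverage = len(table.sites) / n
    logger.info(
        "scored %d kinases; %d/%d sites (%.1f%%) received at least one prediction",
        n_scorable_kinases,
        len(table.sites),
        n,
        100 * coverage,
    )
    return table
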