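"""Benchmarking protocols: leave-one-out cross validation, top-k accuracy,
cross-dataset reproducibility, and multi-dataset consensus.

LOOCV hides one annotated kinase-site association at a time (the hidden
kinase is the *target kinase*), refits the shared-kinase tail model without
it, re-scores the site, and records the rank of the target among all
scorable kinases. A site annotated to several kinases contributes one record
per annotation. Refitting the tail model per fold keeps the hidden edge out
of the estimator, so there is no information leakage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .correlation import CoPhosNetwork, build_cophos_network
from .scoring import collect_shared_kinase_values, fit_tail_model
from .types import (
    KSAnnotation,
    PhosphoProfileMatrix,
    PhosphoSite,
    PredictionTable,
    StaticScoreTable,
)

logger = logging.getLogger(__name__)

SCORERS = ("cophosk", "cophosk_plus")


class LoocvRecord(NamedTuple):
    site: PhosphoSite
    kinase: str          # the hidden target kinase
    rank: int            # rank of the target among scorable kinases (1 = best)
    total: int           # number of scorable kinases for this site


@dataclass
class LoocvResult:
    """Outcome of leave-one-out cross validation over all annotated pairs."""

    records: list[LoocvRecord]
    unevaluable: list[tuple[str, PhosphoSite]] = field(default_factory=list)

    def ranks(self) -> np.ndarray:
        return np.array([r.rank for r in self.records], dtype=int)


def loocv(
    matrix: PhosphoProfileMatrix,
    ksa: KSAnnotation,
    scorer: str = "cophosk",
    static: StaticScoreTable | None = None,
    method: str = "bicor",
    network: CoPhosNetwork | None = None,
) -> LoocvResult:
    """Leave-one-out cross validation of kinase ranking.

    For each annotated (kinase, site) pair with the site measured in the
    network, the single association is removed (the kinase's other
    substrates and the site's other annotations remain), the tail models are
    refit under the reduced annotation, and the target kinase's rank for the
    site is recorded. Associations whose removal leaves the target kinase
    with no measured substrate are recorded as unevaluable, as are targets
    without a static score when the integrated scorer is used.

    Pass a prebuilt ``network`` to skip recomputing correlations.
    """
    if scorer not in SCORERS:
        raise ValueError(f"unknown scorer {scorer!r}; expected one of {SCORERS}")
    if scorer == "cophosk_plus" and static is None:
        raise ValueError("the integrated scorer requires a static score table")
    if network is None:
        network = build_cophos_network(matrix, method=method)
    background = network.condensed()

    records: list[LoocvRecord] = []
    unevaluable: list[tuple[str, PhosphoSite]] = []
    folds = sorted(ksa.associations, key=lambda kp: (kp[0], str(kp[1])))
    for kinase, site in folds:
        if site not in network:
            continue
        reduced = ksa.remove(kinase, site)
        target_neighbours = [
            q for q in reduced.substrates(kinase) if q in network and q != site
        ]
        if not target_neighbours:
            unevaluable.append((kinase, site))
            continue
        try:
            shared = collect_shared_kinase_values(network, reduced)
        except ValueError:
            unevaluable.append((kinase, site))
            continue
        tails = fit_tail_model(background, shared)

        p_idx = network.site_index[site]
        llr_row = tails.log_likelihood_ratio(network.weights[p_idx])
        scores: dict[str, float] = {}
        for k2 in reduced.kinases:
            idx = [
                network.site_index[q]
                for q in reduced.substrates(k2)
                if q in network and q != site
            ]
            if not idx:
                continue
            h = math.fsum(llr_row[np.array(sorted(idx))])
            if scorer == "cophosk_plus":
                x = static.get(k2, site)
                if x is None:
                    continue
                h += math.log2(x)
            scores[k2] = h
        if kinase not in scores:
            unevaluable.append((kinase, site))
            continue
        ordering = sorted(scores, key=lambda k: (-scores[k], k))
        records.append(
            LoocvRecord(
                site=site,
                kinase=kinase,
                rank=ordering.index(kinase) + 1,
                total=len(scores),
            )
        )
    logger.info(
        "LOOCV: %d associations evaluated, %d unevaluable",
        len(records),
        len(unevaluable),
    )
    return LoocvResult(records=records, unevaluable=unevaluable)


def topk_accuracy(result: LoocvResult, k: int) -> float:
    """Fraction of hidden associations whose target kinase ranks in the top k."""
    if not result.records:
        raise ValueError("empty LOOCV result")
    ranks = result.ranks()
    return float(np.mean(ranks <= k))


class ReproducibilityResult(NamedTuple):
    top1_match_rate: float     # identical top-ranked kinase in both datasets
    top1_in_top5_rate: float   # A's top-1 within B's top 5
    n_common: int


def cross_dataset_reproducibility(
    pred_a: PredictionTable, pred_b: PredictionTable
) -> ReproducibilityResult:
    """Agreement of per-site predictions across two independent datasets."""
    common = sorted(pred_a.sites & pred_b.sites, key=str)
    if not common:
        raise ValueError("no site is ranked in both prediction tables")
    top1_match = sum(
        pred_a.top(site)[0] == pred_b.top(site)[0] for site in common
    )
    top1_in_top5 = sum(
        pred_a.top(site)[0] in pred_b.top(site, 5) for site in common
    )
    n = len(common)
    return ReproducibilityResult(top1_match / n, top1_in_top5 / n, n)


@dataclass(frozen=True)
class CategoryCounts:
    """Per-dataset top-1 prediction categories against the annotation.

    cat1: top-ranked kinase matches ANY annotated kinase of the site;
    cat2: the site is annotated but the top-ranked kinase disagrees;
    cat3: the site has no annotation.
    """

    cat1: int
    cat2: int
    cat3: int

    @property
    def precision(self) -> float:
        annotated = self.cat1 + self.cat2
        return self.cat1 / annotated if annotated else float("nan")


@dataclass(frozen=True)
class SupportCounts:
    """Sites predicted by exactly j datasets, split by annotation status."""

    n_annotated: int
    n_unannotated: int
    identical_annotated: int    # identical top-1 across all j datasets
    identical_unannotated: int
    true_identical: int         # identical AND matching an annotated kinase

    @property
    def precision(self) -> float:
        return (
            self.true_identical / self.identical_annotated
            if self.identical_annotated
            else float("nan")
        )


@dataclass
class ConsensusReport:
    per_dataset: list[CategoryCounts]
    by_support: dict[int, SupportCounts]


def consensus(
    preds: Sequence[PredictionTable], ksa: KSAnnotation
) -> ConsensusReport:
    """Multi-dataset consensus of top-1 predictions.

    Each dataset's top-1 predictions are categorized against the annotation
    (any-match rule: agreement with any annotated kinase of the site counts
    as correct). Sites are then stratified by how many datasets predict
    them, counting those whose top-ranked kinase is identical across all
    supporting datasets and, among annotated sites, how many of those
    identical calls match the annotation.
    """
    if not preds:
        raise ValueError("at least one prediction table is required")
    per_dataset = []
    for table in preds:
        cat1 = cat2 = cat3 = 0
        for site in table.sites:
            annotated = ksa.kinases_of(site)
            if not annotated:
                cat3 += 1
            elif table.top(site)[0] in annotated:
                cat1 += 1
            else:
                cat2 += 1
        per_dataset.append(CategoryCounts(cat1=cat1, cat2=cat2, cat3=cat3))

    all_sites = set().union(*(t.sites for t in preds))
    by_support: dict[int, dict[str, int]] = {}
    for site in all_sites:
        tops = [t.top(site)[0] for t in preds if site in t.sites]
        j = len(tops)
        bucket = by_support.setdefault(
            j,
            {
                "n_annotated": 0,
                "n_unannotated": 0,
                "identical_annotated": 0,
                "identical_unannotated": 0,
                "true_identical": 0,
            },
        )
        annotated = ksa.kinases_of(site)
        identical = len(set(tops)) == 1
        if annotated:
            bucket["n_annotated"] += 1
            if identical:
                bucket["identical_annotated"] += 1
                if tops[0] in annotated:
                    bucket["true_identical"] += 1
        else:
            bucket["n_unannotated"] += 1
            if identical:
                bucket["identical_unannotated"] += 1
    return ConsensusReport(
        per_dataset=per_dataset,
        by_support={j: SupportCounts(**b) for j, b in sorted(by_support.items())},
    )
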