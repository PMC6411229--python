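"""Integration of co-phosphorylation scores with static kinase-site scores.

Static predictors (sequence-motif plus protein-network evidence) and
co-phosphorylation carry largely orthogonal information. The integrated
score simply adds the two log-scale terms:

    M(k, p) = h(k, p) + log2(x(k, p))

where h is the co-phosphorylation log-likelihood score and x > 0 is the
static score. Integrated predictions exist only where BOTH inputs score the
(kinase, site) pair, so coverage is the static table's coverage intersected
with the scorable pairs.
"""

from __future__ import annotations

import math

from .types import PhosphoSite, PredictionTable, StaticScoreTable


def combine_scores(
    h_table: PredictionTable,
    static: StaticScoreTable,
    static_only_fallback: bool = False,
) -> PredictionTable:
    """Integrated prediction table with M(k, p) = h(k, p) + log2(x(k, p)).

    Pairs missing from either input are absent from the result. With
    ``static_only_fallback``, pairs that have a static score but no
    co-phosphorylation score are kept with h substituted by 0 (a pure
    static-score ranking for those pairs). Per-site ranking uses the same
    descending-score, ascending-kinase-name tie-break as the base scorer.
    """
    if len(h_table.entries) == 0 or len(static) == 0:
        raise ValueError("both score tables must be non-empty")
    entries: dict[tuple[str, PhosphoSite], float] = {}
    for (kinase, site), x in static.scores.items():
        h = h_table.entries.get((kinase, site))
        if h is None:
            if not static_only_fallback:
                continue
            h = 0.0
        entries[(kinase, site)] = h + math.log2(x)
    if not entries:
        raise ValueError(
            "no (kinase, site) pair is scorable in both the "
            "co-phosphorylation and static tables"
        )
    return PredictionTable.from_scores(entries)
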