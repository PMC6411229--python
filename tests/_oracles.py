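"""Independent reference implementations used only to check the package.

Everything here is written as plain scalar loops over Python floats, with no
helpers shared with the package, so agreement between the two code paths is
meaningful evidence of correctness.
"""

from __future__ import annotations

import math
from statistics import median


def bicor_scalar(x, y) -> float:
    """Straight-line transcription of the biweight midcorrelation definition.

    c_xy = sum_i x'_i y'_i with
    x'_i = (x_i - med(x)) w_i / sqrt(sum_j [(x_j - med(x)) w_j]^2),
    w_i = (1 - u_i^2)^2 I(1 - |u_i| > 0), u_i = (x_i - med(x)) / (9 mad(x)).
    """

    def standardize(v):
        v = [float(a) for a in v]
        med = median(v)
        mad = median([abs(a - med) for a in v])
        if mad == 0:
            raise ValueError("degenerate vector")
        weighted = []
        for a in v:
            u = (a - med) / (9.0 * mad)
            indicator = 1.0 if (1.0 - abs(u)) > 0 else 0.0
            w = (1.0 - u * u) ** 2 * indicator
            weighted.append((a - med) * w)
        denom = math.sqrt(sum(t * t for t in weighted))
        return [t / denom for t in weighted]

    xs = standardize(x)
    ys = standardize(y)
    return sum(a * b for a, b in zip(xs, ys))


def pearson_textbook(x, y) -> float:
    """Product-moment correlation from the textbook definition."""
    x = [float(a) for a in x]
    y = [float(a) for a in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def ks_d_bruteforce(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by a naive double-loop sweep over all values."""
    a = sorted(float(v) for v in a)
    b = sorted(float(v) for v in b)
    d = 0.0
    for t in a + b:
        fa = sum(1 for v in a if v <= t) / len(a)
        fb = sum(1 for v in b if v <= t) / len(b)
        d = max(d, abs(fa - fb))
    return d


def survival_countloop(sample, c) -> float:
    """Add-one survival (#{v > c} + 1) / (n + 1) by explicit counting."""
    sample = [float(v) for v in sample]
    n = len(sample)
    greater = sum(1 for v in sample if v > c)
    s = (greater + 1) / (n + 1)
    eps = 1 / (n + 1)
    return min(1.0, max(eps, s))


def shared_kinase_values_bruteforce(weights, sites, ksa):
    """Double loop over all site pairs checking shared-kinase membership."""
    values = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if ksa.kinases_of(sites[i]) & ksa.kinases_of(sites[j]):
                values.append(float(weights[i][j]))
    return values


def exhaustive_predictions(weights, sites, ksa):
    """Exhaustive kinase-site scoring by triple loop.

    Builds the background and shared-kinase samples by brute force, scores
    every (kinase, site) pair by summing log2 survival ratios over the
    kinase's other measured substrates (ascending site index), and ranks per
    site by descending score then ascending kinase name. Returns
    (scores dict, ranks dict).
    """
    n = len(sites)
    background = [
        float(weights[i][j]) for i in range(n) for j in range(i + 1, n)
    ]
    shared = shared_kinase_values_bruteforce(weights, sites, ksa)
    scores = {}
    for kinase in sorted(ksa.kinases):
        substrates = ksa.substrates(kinase)
        for p_i, p in enumerate(sites):
            terms = []
            for q_i, q in enumerate(sites):
                if q_i == p_i or q not in substrates:
                    continue
                c = float(weights[p_i][q_i])
                terms.append(math.log2(
                    survival_countloop(shared, c)
                    / survival_countloop(background, c)
                ))
            if terms:
                scores[(kinase, p)] = math.fsum(terms)
    per_site = {}
    for (kinase, site), score in scores.items():
        per_site.setdefault(site, []).append((kinase, score))
    ranks = {
        site: [k for k, _ in sorted(pairs, key=lambda kv: (-kv[1], kv[0]))]
        for site, pairs in per_site.items()
    }
    return scores, ranks
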