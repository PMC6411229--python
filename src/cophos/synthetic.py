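"""Synthetic phosphoproteomics data with planted kinase structure.

The generator emulates the statistical structure the prediction method
relies on: substrates of the same kinase have correlated phosphorylation
profiles, so shared-kinase pairs form a right-shifted co-phosphorylation
distribution relative to the background of unrelated site pairs.

It is a latent factor model: each kinase k has an activity factor f_k across
the m biological states (i.i.d. standard normal), and a substrate's profile
is

    profile = sqrt(rho) * s * f + sqrt(1 - rho) * noise

with loading sign s = -1 for "negative regulator" sites (sites whose
phosphorylation runs opposite to the kinase activity, as with
phosphatase-coupled or inhibitory sites) and f the kinase factor - or, for
multi-kinase sites, the variance-preserving average (f_k1 + f_k2)/sqrt(2) of
two factors. Background sites are pure noise. The expected profile
correlation of two plain substrates of the same kinase is therefore exactly
rho, and 0 for background pairs, which gives closed-form targets for tests.

Static kinase-site scores are generated as
x(k, p) = exp(informativeness * z_true + (1 - informativeness) * z_noise)
with z_true = 2 for true kinase-site pairs and 0 otherwise and
z_noise ~ N(0, 1): informativeness 1 gives a cleanly separating static
predictor, 0 gives pure positive noise.

Not modelled: missing values, iTRAQ/TMT ratio compression, or any other
acquisition noise - inputs are assumed post-quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .types import (
    KSAnnotation,
    PhosphoProfileMatrix,
    PhosphoSite,
    StaticScoreTable,
)

#: Latent separation between true and non-true kinase-site pairs in the
#: static score model (log scale).
STATIC_TRUE_SIGNAL = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults describe a mid-sized quantitative phosphoproteomics design:
    20 biological states, 10 kinases with 20 measured substrates each, 200
    unannotated background sites, and within-kinase profile correlation 0.7
    (a strongly coordinated kinase program).
    """

    n_states: int = 20
    n_kinases: int = 10
    substrates_per_kinase: int = 20
    n_background: int = 200
    within_kinase_correlation: float = 0.7
    multi_kinase_fraction: float = 0.0
    negative_regulator_fraction: float = 0.0
    static_score_informativeness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 3:
            raise ValueError("n_states must be >= 3")
        for name in ("n_kinases", "substrates_per_kinase", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "within_kinase_correlation",
            "multi_kinase_fraction",
            "negative_regulator_fraction",
            "static_score_informativeness",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


class SyntheticDataset(NamedTuple):
    matrix: PhosphoProfileMatrix
    annotation: KSAnnotation
    static_scores: StaticScoreTable
    truth: dict[PhosphoSite, str]  # primary generating kinase per substrate site


def _site(index: int) -> PhosphoSite:
    residue = "STY"[index % 3]
    return PhosphoSite(
        protein=f"PROT{index:05d}", residue=residue, position=index + 1
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate (matrix, annotation, static scores, truth), reproducibly.

    The annotation contains every true kinase-site association (use
    :func:`annotation_subsample` to emulate an incomplete database). ``truth``
    maps each substrate site to its primary kinase; multi-kinase sites carry
    a second association in the annotation but keep their primary kinase in
    ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_states
    rho = config.within_kinase_correlation
    kinases = [f"KIN{k + 1:02d}" for k in range(config.n_kinases)]
    factors = rng.standard_normal((config.n_kinases, m))

    sites: list[PhosphoSite] = []
    profiles: list[np.ndarray] = []
    associations: list[tuple[str, PhosphoSite]] = []
    truth: dict[PhosphoSite, str] = {}

    index = 0
    for k, kinase in enumerate(kinases):
        for _ in range(config.substrates_per_kinase):
            site = _site(index)
            index += 1
            factor = factors[k]
            associations.append((kinase, site))
            truth[site] = kinase
            if config.n_kinases > 1 and rng.random() < config.multi_kinase_fraction:
                k2 = int(rng.integers(config.n_kinases - 1))
                if k2 >= k:
                    k2 += 1
                factor = (factors[k] + factors[k2]) / np.sqrt(2.0)
                associations.append((kinases[k2], site))
            sign = -1.0 if rng.random() < config.negative_regulator_fraction else 1.0
            noise = rng.standard_normal(m)
            profiles.append(
                np.sqrt(rho) * sign * factor + np.sqrt(1.0 - rho) * noise
            )
            sites.append(site)
    for _ in range(config.n_background):
        site = _site(index)
        index += 1
        sites.append(site)
        profiles.append(rng.standard_normal(m))

    matrix = PhosphoProfileMatrix(
        sites=sites,
        states=[f"state{j + 1:02d}" for j in range(m)],
        values=np.vstack(profiles) if profiles else np.empty((0, m)),
    )
    annotation = KSAnnotation.from_pairs(associations)

    info = config.static_score_informativeness
    true_pairs = set(associations)
    scores: dict[tuple[str, PhosphoSite], float] = {}
    for kinase in kinases:
        for site in sites:
            z_true = STATIC_TRUE_SIGNAL if (kinase, site) in true_pairs else 0.0
            z_noise = rng.standard_normal()
            scores[(kinase, site)] = float(
                np.exp(info * z_true + (1.0 - info) * z_noise)
            )
    return SyntheticDataset(
        matrix=matrix,
        annotation=annotation,
        static_scores=StaticScoreTable(scores=scores),
        truth=truth,
    )


def annotation_subsample(
    ksa: KSAnnotation,
    keep_fraction: float,
    seed: int,
    min_substrates: int = 2,
) -> KSAnnotation:
    """Uniformly subsample associations, emulating an incomplete database.

    Each association is kept independently with probability
    ``keep_fraction``; the minimum-substrate kinase filter is re-applied so
    the result satisfies the annotation eligibility invariant.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if keep_fraction == 1.0:
        return ksa
    rng = np.random.default_rng(seed)
    ordered = sorted(ksa.associations, key=lambda kp: (kp[0], str(kp[1])))
    kept = [pair for pair in ordered if rng.random() < keep_fraction]
    return KSAnnotation.from_pairs(kept).filter_min_substrates(min_substrates)
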