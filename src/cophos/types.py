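"""Core domain containers for co-phosphorylation analysis.

The analysis operates on three kinds of objects: phosphosites (a specific
serine/threonine/tyrosine residue on a protein), the phosphorylation-profile
matrix (fold-change levels of each site across biological states), and
kinase-substrate annotations (which kinase is reported to phosphorylate
which site). A static kinase-site score table (sequence/interaction-based
likelihoods from an external predictor) is an optional fourth input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import numpy as np

PHOSPHO_RESIDUES = frozenset("STY")

#: Number of biological states below which profile correlations are
#: considered too noisy to be informative.
RECOMMENDED_MIN_STATES = 5


@dataclass(frozen=True, order=True)
class PhosphoSite:
    """One measured phosphorylation site: protein + residue + 1-based position.

    The canonical string form is ``<protein>_<residue><position>``,
    e.g. ``NDRG1_S330``; :meth:`parse` and ``str()`` round-trip losslessly.
    Isoform suffixes on the protein identifier are kept verbatim.
    """

    protein: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError("empty protein identifier")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"residue must be one of S/T/Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @classmethod
    def parse(cls, token: str) -> "PhosphoSite":
        """Parse the canonical ``PROT_S330`` form (last underscore splits)."""
        token = token.strip()
        if "_" not in token:
            raise ValueError(f"malformed site identifier {token!r}")
        protein, site_token = token.rsplit("_", 1)
        if len(site_token) < 2:
            raise ValueError(f"malformed site identifier {token!r}")
        residue, pos_str = site_token[0], site_token[1:]
        if residue not in PHOSPHO_RESIDUES or not pos_str.isdigit():
            raise ValueError(f"malformed site identifier {token!r}")
        return cls(protein=protein, residue=residue, position=int(pos_str))

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}"


@dataclass
class PhosphoProfileMatrix:
    """Sites x states matrix of fold-change phosphorylation levels.

    A site's row is its *phosphorylation profile*: the vector of its
    phosphorylation levels (fold-changes versus a reference, optionally
    log-transformed) across the biological states of the experiment.

    Invariants enforced at construction: no missing values, no duplicate
    sites, at least 3 states.  A warning is emitted below
    :data:`RECOMMENDED_MIN_STATES` states, where correlation estimates
    become unreliable.
    """

    sites: list[PhosphoSite]
    states: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.sites), len(self.states)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} sites x {m} states"
            )
        if m < 3:
            raise ValueError(f"at least 3 states required, got {m}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite entries")
        if len(set(self.sites)) != n:
            raise ValueError("duplicate sites in matrix")
        if m < RECOMMENDED_MIN_STATES:
            warnings.warn(
                f"only {m} biological states; at least "
                f"{RECOMMENDED_MIN_STATES} are recommended for reliable "
                "co-phosphorylation estimates",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @cached_property
    def site_index(self) -> dict[PhosphoSite, int]:
        return {s: i for i, s in enumerate(self.sites)}

    def profile(self, site: PhosphoSite) -> np.ndarray:
        """Return the phosphorylation profile (row) of ``site``."""
        return self.values[self.site_index[site]]

    def subset_states(self, state_indices: Iterable[int]) -> "PhosphoProfileMatrix":
        """Matrix restricted to a subset of state columns (profile subsampling)."""
        idx = list(state_indices)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return PhosphoProfileMatrix(
                sites=list(self.sites),
                states=[self.states[j] for j in idx],
                values=self.values[:, idx].copy(),
            )


@dataclass(frozen=True)
class KSAnnotation:
    """Kinase -> substrate-site annotation (the prior knowledge base).

    ``sites`` is the union of all annotated sites (the set T);
    :meth:`substrates` gives the substrate set of one kinase (T_k).
    """

    associations: frozenset[tuple[str, PhosphoSite]]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, PhosphoSite]]
    ) -> "KSAnnotation":
        return cls(associations=frozenset(pairs))

    @cached_property
    def _by_kinase(self) -> dict[str, frozenset[PhosphoSite]]:
        acc: dict[str, set[PhosphoSite]] = {}
        for kinase, site in self.associations:
            acc.setdefault(kinase, set()).add(site)
        return {k: frozenset(v) for k, v in acc.items()}

    @property
    def kinases(self) -> frozenset[str]:
        return frozenset(self._by_kinase)

    @cached_property
    def sites(self) -> frozenset[PhosphoSite]:
        return frozenset(site for _, site in self.associations)

    def substrates(self, kinase: str) -> frozenset[PhosphoSite]:
        return self._by_kinase.get(kinase, frozenset())

    @cached_property
    def _by_site(self) -> dict[PhosphoSite, frozenset[str]]:
        acc: dict[PhosphoSite, set[str]] = {}
        for kinase, site in self.associations:
            acc.setdefault(site, set()).add(kinase)
        return {s: frozenset(v) for s, v in acc.items()}

    def kinases_of(self, site: PhosphoSite) -> frozenset[str]:
        return self._by_site.get(site, frozenset())

    def filter_min_substrates(self, min_substrates: int = 2) -> "KSAnnotation":
        """Drop kinases with fewer than ``min_substrates`` annotated sites."""
        keep = {
            k for k, subs in self._by_kinase.items()
            if len(subs) >= min_substrates
        }
        return KSAnnotation.from_pairs(
            (k, s) for k, s in self.associations if k in keep
        )

    def remove(self, kinase: str, site: PhosphoSite) -> "KSAnnotation":
        """Annotation with the single (kinase, site) association removed."""
        return KSAnnotation(associations=self.associations - {(kinase, site)})

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[tuple[str, PhosphoSite]]:
        return iter(self.associations)


@dataclass(frozen=True)
class StaticScoreTable:
    """Kinase-site scores from a static (sequence/interaction) predictor.

    Scores x(k, p) must be strictly positive: they enter the integrated
    score through log2(x).
    """

    scores: Mapping[tuple[str, PhosphoSite], float]

    def __post_init__(self) -> None:
        for key, x in self.scores.items():
            if not x > 0:
                raise ValueError(f"non-positive static score {x} for {key}")

    def get(self, kinase: str, site: PhosphoSite) -> float | None:
        return self.scores.get((kinase, site))

    def __len__(self) -> int:
        return len(self.scores)

    @cached_property
    def sites(self) -> frozenset[PhosphoSite]:
        return frozenset(site for _, site in self.scores)


@dataclass
class PredictionTable:
    """Per-(kinase, site) scores plus per-site kinase rankings.

    Rankings sort scores in descending order; ties break on ascending
    kinase name so output is deterministic.  Rank 1 is the best kinase.
    """

    entries: dict[tuple[str, PhosphoSite], float]
    ranks: dict[PhosphoSite, list[str]] = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls, entries: Mapping[tuple[str, PhosphoSite], float]
    ) -> "PredictionTable":
        per_site: dict[PhosphoSite, list[tuple[str, float]]] = {}
        for (kinase, site), score in entries.items():
            per_site.setdefault(site, []).append((kinase, score))
        ranks = {
            site: [k for k, _ in sorted(pairs, key=lambda kv: (-kv[1], kv[0]))]
            for site, pairs in per_site.items()
        }
        return cls(entries=dict(entries), ranks=ranks)

    @property
    def sites(self) -> frozenset[PhosphoSite]:
        return frozenset(self.ranks)

    def top(self, site: PhosphoSite, k: int = 1) -> list[str]:
        """The k best-ranked kinases for ``site``."""
        return self.ranks[site][:k]

    def score(self, kinase: str, site: PhosphoSite) -> float | None:
        return self.entries.get((kinase, site))

    def to_records(self) -> list[tuple[PhosphoSite, int, str, float]]:
        """Flatten to (site, rank, kinase, score), sorted by (site, rank)."""
        records = []
        for site in sorted(self.ranks, key=str):
            for rank, kinase in enumerate(self.ranks[site], start=1):
                records.append((site, rank, kinase, self.entries[(kinase, site)]))
        return records
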