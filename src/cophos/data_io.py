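"""Readers and writers for the TSV dialects the pipeline consumes.

All tables are UTF-8, tab-delimited, '.' decimal:

- intensity matrix: header ``site<TAB>sample1<TAB>...``; one row per
  phosphosite in canonical ``PROT_S330`` form, cells numeric or empty;
- kinase-substrate annotation: header ``kinase<TAB>substrate<TAB>site``
  (site = residue letter + position, e.g. ``S330``);
- static scores: header ``kinase<TAB>site_id<TAB>score``;
- predictions: header ``site_id<TAB>rank<TAB>kinase<TAB>score``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    KSAnnotation,
    PhosphoProfileMatrix,
    PhosphoSite,
    PredictionTable,
    StaticScoreTable,
)

logger = logging.getLogger(__name__)


def read_intensity_matrix(
    path: str | Path, log_transform: bool = False
) -> PhosphoProfileMatrix:
    """Read a phosphosite x state fold-change matrix.

    Rows with any empty or non-numeric cell are dropped (completeness
    filter); duplicate site rows are aggregated by element-wise mean;
    ``log_transform`` replaces values by log2 and requires all retained
    values to be positive. Drop/aggregation counts are logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 1 or df.columns[0] != "site":
        raise ValueError(
            f"{path}: malformed header; first column must be 'site', "
            f"got {list(df.columns[:1])!r}"
        )
    state_cols = list(df.columns[1:])
    if len(state_cols) < 3:
        raise ValueError(
            f"{path}: at least 3 state columns required, got {len(state_cols)}"
        )
    values = df[state_cols].apply(pd.to_numeric, errors="coerce")
    complete = values.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d rows with missing or non-numeric values",
            path,
            n_dropped,
            len(df),
        )
    kept = pd.DataFrame(values[complete])
    kept.insert(0, "site", df.loc[complete, "site"])

    n_before = len(kept)
    aggregated = kept.groupby("site", sort=False, as_index=True).mean()
    n_dup = n_before - len(aggregated)
    if n_dup:
        logger.info("%s: aggregated %d duplicate site rows by mean", path, n_dup)

    sites = [PhosphoSite.parse(token) for token in aggregated.index]
    matrix_values = aggregated.to_numpy(dtype=float)
    if log_transform:
        if np.any(matrix_values <= 0):
            bad = np.argwhere(matrix_values <= 0)[0]
            raise ValueError(
                f"{path}: non-positive value in row {str(sites[bad[0]])!r}, "
                f"column {state_cols[bad[1]]!r}; cannot log-transform"
            )
        matrix_values = np.log2(matrix_values)
    return PhosphoProfileMatrix(
        sites=sites, states=state_cols, values=matrix_values
    )


def read_ksa_table(path: str | Path, min_substrates: int = 2) -> KSAnnotation:
    """Read a kinase-substrate annotation table.

    Duplicate rows collapse (set semantics); kinases with fewer than
    ``min_substrates`` distinct substrate sites are removed, mirroring the
    eligibility rule that a kinase needs at least two reported substrates to
    support co-phosphorylation evidence.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["kinase", "substrate", "site"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: malformed header; expected columns {required}, "
            f"got {list(df.columns[:3])!r}"
        )
    if df.empty:
        warnings.warn(f"{path}: empty annotation table", UserWarning, stacklevel=2)
        return KSAnnotation.from_pairs([])
    pairs = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        token = f"{row.substrate}_{row.site}"
        try:
            site = PhosphoSite.parse(token)
        except ValueError as err:
            raise ValueError(f"{path}, line {line_no}: {err}") from None
        pairs.append((str(row.kinase), site))
    full = KSAnnotation.from_pairs(pairs)
    filtered = full.filter_min_substrates(min_substrates)
    n_removed = len(full.kinases) - len(filtered.kinases)
    if n_removed:
        logger.info(
            "%s: removed %d/%d kinases with fewer than %d substrates",
            path,
            n_removed,
            len(full.kinases),
            min_substrates,
        )
    return filtered


def read_static_scores(path: str | Path) -> StaticScoreTable:
    """Read a static kinase-site score table.

    Entries with score <= 0 are skipped (they cannot enter the log2 of the
    integrated score) and counted in the log. A (kinase, site) key appearing
    twice with different scores is refused as ambiguous.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["kinase", "site_id", "score"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: malformed header; expected columns {required}, "
            f"got {list(df.columns[:3])!r}"
        )
    scores: dict[tuple[str, PhosphoSite], float] = {}
    n_skipped = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, line {line_no}: non-numeric score {row.score!r}"
            ) from None
        try:
            site = PhosphoSite.parse(str(row.site_id))
        except ValueError as err:
            raise ValueError(f"{path}, line {line_no}: {err}") from None
        if score <= 0:
            n_skipped += 1
            continue
        key = (str(row.kinase), site)
        if key in scores and scores[key] != score:
            raise ValueError(
                f"{path}, line {line_no}: duplicate entry for kinase "
                f"{key[0]!r}, site {site} with conflicting scores"
            )
        scores[key] = score
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} entries with non-positive scores",
            UserWarning,
            stacklevel=2,
        )
        logger.info("%s: skipped %d non-positive scores", path, n_skipped)
    return StaticScoreTable(scores=scores)


PREDICTIONS_HEADER = "site_id\trank\tkinase\tscore"


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    """Write a prediction table as deterministic TSV.

    Rows are sorted by (canonical site string, rank); scores are written
    with shortest round-tripping repr so read-back reproduces the table
    bit-exactly.
    """
    path = Path(path)
    lines = [PREDICTIONS_HEADER]
    for site, rank, kinase, score in table.to_records():
        lines.append(f"{site}\t{rank}\t{kinase}\t{score!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_predictions(path: str | Path) -> PredictionTable:
    """Read a prediction TSV written by :func:`write_predictions`."""
    path = Path(path)
    entries: dict[tuple[str, PhosphoSite], float] = {}
    ranks: dict[PhosphoSite, list[tuple[int, str]]] = {}
    with path.open(encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header != PREDICTIONS_HEADER:
            raise ValueError(f"{path}: malformed predictions header {header!r}")
        for line_no, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}, line {line_no}: expected 4 fields")
            site = PhosphoSite.parse(fields[0])
            rank, kinase, score = int(fields[1]), fields[2], float(fields[3])
            entries[(kinase, site)] = score
            ranks.setdefault(site, []).append((rank, kinase))
    ordered = {
        site: [k for _, k in sorted(pairs)] for site, pairs in ranks.items()
    }
    return PredictionTable(entries=entries, ranks=ordered)


def write_matrix(matrix: PhosphoProfileMatrix, path: str | Path) -> None:
    """Write a profile matrix in the intensity-matrix TSV dialect."""
    path = Path(path)
    lines = ["site\t" + "\t".join(matrix.states)]
    for site, row in zip(matrix.sites, matrix.values):
        lines.append(str(site) + "\t" + "\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_ksa_table(ksa: KSAnnotation, path: str | Path) -> None:
    """Write an annotation in the KSA TSV dialect (sorted, deterministic)."""
    path = Path(path)
    lines = ["kinase\tsubstrate\tsite"]
    for kinase, site in sorted(ksa.associations, key=lambda kp: (kp[0], str(kp[1]))):
        lines.append(f"{kinase}\t{site.protein}\t{site.residue}{site.position}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_static_scores(table: StaticScoreTable, path: str | Path) -> None:
    """Write a static score table in its TSV dialect (sorted, deterministic)."""
    path = Path(path)
    lines = ["kinase\tsite_id\tscore"]
    for (kinase, site), score in sorted(
        table.scores.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        lines.append(f"{kinase}\t{site}\t{score!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
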