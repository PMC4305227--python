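"""Per-gene fold changes across the ten comparison pairs.

Fold change is computed on gene-level log2 expression as
``2 ** |mean_A - mean_B|`` of the two group means, reported as a ratio
>= 1 with an explicit direction (up / down / flat).  All thresholds in
this package are inclusive (a gene at exactly the threshold fold is
kept), matching the convention of the fold-change filtering the panels
are built on.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ComparisonPair, StudyDesign, TEN_PAIRS

UP = "up"
DOWN = "down"
FLAT = "flat"

#: Columns of a long-format fold-change record table.
RECORD_COLUMNS = ("gene_id", "pair", "ratio", "direction")


class DiffexpError(ValueError):
    """Raised for invalid fold-change inputs (empty group, bad threshold)."""


def fold_change(
    gene_matrix: pd.DataFrame, design: StudyDesign, pair: ComparisonPair
) -> pd.DataFrame:
    """Fold change of every gene for one comparison pair.

    Parameters
    ----------
    gene_matrix:
        Genes x samples log2 expression.
    design:
        Sample-to-group assignment; both groups of ``pair`` must have at
        least one sample present in the matrix.

    Returns
    -------
    Long-format records with columns ``gene_id, pair, ratio, direction``;
    ratio is ``2 ** |diff|`` of the group mean log2 values.
    """
    cols = {}
    for group in (pair.numerator, pair.denominator):
        samples = [s for s in design.samples_in(group) if s in gene_matrix.columns]
        if not samples:
            raise DiffexpError(f"group {group!r} has no samples in the matrix")
        cols[group] = samples
    diff = (
        gene_matrix[cols[pair.numerator]].mean(axis=1)
        - gene_matrix[cols[pair.denominator]].mean(axis=1)
    ).to_numpy()
    direction = np.where(diff > 0, UP, np.where(diff < 0, DOWN, FLAT))
    return pd.DataFrame(
        {
            "gene_id": gene_matrix.index,
            "pair": pair.label,
            "ratio": np.exp2(np.abs(diff)),
            "direction": direction,
        }
    )


def fold_change_table(
    gene_matrix: pd.DataFrame,
    design: StudyDesign,
    pairs: Iterable[ComparisonPair] = TEN_PAIRS,
) -> pd.DataFrame:
    """Concatenated fold-change records for several comparison pairs."""
    return pd.concat(
        [fold_change(gene_matrix, design, pair) for pair in pairs],
        ignore_index=True,
    )


def filter_genes(
    records: pd.DataFrame,
    pair: ComparisonPair | str,
    direction: str,
    threshold: float,
) -> list[str]:
    """Genes changed in ``direction`` by at least ``threshold``-fold.

    The threshold is inclusive; flat genes never match either direction.
    """
    if threshold < 1:
        raise DiffexpError(f"fold threshold must be >= 1, got {threshold}")
    if direction not in (UP, DOWN):
        raise DiffexpError(f"direction must be {UP!r} or {DOWN!r}, got {direction!r}")
    label = pair if isinstance(pair, str) else pair.label
    mask = (
        (records["pair"] == label)
        & (records["direction"] == direction)
        & (records["ratio"] >= threshold)
    )
    return list(records.loc[mask, "gene_id"])


def threshold_census(
    records: pd.DataFrame,
    direction: str,
    thresholds: Sequence[float],
    pairs: Iterable[ComparisonPair] = TEN_PAIRS,
) -> pd.DataFrame:
    """Count genes per (pair, threshold) for one direction.

    Reproduces the structure of the study's census tables: rows are the
    comparison pairs, columns the ascending fold thresholds, cells the
    number of genes at or above the threshold in the given direction.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise DiffexpError("thresholds must be sorted ascending")
    counts = {
        pair.label: [
            len(filter_genes(records, pair, direction, t)) for t in thresholds
        ]
        for pair in pairs
    }
    return pd.DataFrame.from_dict(
        counts, orient="index", columns=[f">={t:g}" for t in thresholds]
    ).rename_axis("pair")
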