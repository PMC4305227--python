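"""Co-differential biomarker panel selection.

A gene enters a panel when it moves in the same direction in *every*
comparison of a designated set and its weakest (minimum) fold across the
set reaches the panel threshold.  Two panels are defined by the study
design:

* **COPD-specific** — consistent change in all four disease-vs-control
  comparisons (stable COPD and each exacerbation day vs controls).
* **AECOPD-specific** — consistent change in all six exacerbation
  comparisons (each exacerbation day vs both controls and stable COPD).

Selection operates on whatever row identity the fold-change records
carry (array sequence ids in the original platform), so several rows may
map to one gene symbol; a symbol-deduplicated count is reported
alongside the row-level panel.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .design import AECOPD_COMPARISONS, COPD_COMPARISONS, ComparisonPair
from .diffexp import DOWN, UP


class PanelError(ValueError):
    """Raised for invalid panel specifications or incomplete records."""


@dataclass(frozen=True)
class PanelSpec:
    """Comparison set and fold thresholds defining one panel."""

    name: str
    comparisons: tuple[ComparisonPair, ...]
    up_threshold: float
    down_threshold: float

    def __post_init__(self) -> None:
        if self.up_threshold < 1 or self.down_threshold < 1:
            raise PanelError("panel thresholds must be >= 1")
        if not self.comparisons:
            raise PanelError("panel needs at least one comparison")


def copd_spec(up_threshold: float = 10.0, down_threshold: float = 10.0) -> PanelSpec:
    return PanelSpec("copd_specific", COPD_COMPARISONS, up_threshold, down_threshold)


def aecopd_spec(up_threshold: float = 10.0, down_threshold: float = 3.0) -> PanelSpec:
    return PanelSpec("aecopd_specific", AECOPD_COMPARISONS, up_threshold, down_threshold)


@dataclass(frozen=True)
class MinFold:
    """Weakest fold of a gene over a comparison set, if direction-consistent."""

    fold: float
    direction: str
    qualified: bool


DISQUALIFIED = MinFold(math.nan, "mixed", False)


def min_fold(
    gene_id: str, records: pd.DataFrame, comparisons: Iterable[ComparisonPair | str]
) -> MinFold:
    """Minimum ratio of one gene across a comparison set.

    Valid only when the gene moves in the same (non-flat) direction in
    every comparison; otherwise the disqualified sentinel is returned.
    A missing comparison is an error: co-differential selection is only
    meaningful over complete record sets.
    """
    labels = [c if isinstance(c, str) else c.label for c in comparisons]
    sub = records[records["gene_id"] == gene_id].set_index("pair")
    missing = [lab for lab in labels if lab not in sub.index]
    if missing:
        raise PanelError(f"gene {gene_id!r} lacks records for {missing}")
    sub = sub.loc[labels]
    directions = set(sub["direction"])
    if len(directions) != 1 or directions & {"flat"}:
        return DISQUALIFIED
    return MinFold(float(sub["ratio"].min()), directions.pop(), True)


@dataclass
class Panel:
    """Result of a panel selection: row-level gene tables per direction."""

    spec: PanelSpec
    up: pd.DataFrame = field(repr=False)
    down: pd.DataFrame = field(repr=False)

    def symbol_counts(self, symbols: Mapping[str, str] | None = None) -> dict[str, int]:
        """Row-level and symbol-deduplicated panel sizes.

        ``symbols`` maps row id -> gene symbol; without it the symbol
        counts equal the row counts.
        """
        out = {"up_rows": len(self.up), "down_rows": len(self.down)}
        for direction, table in (("up", self.up), ("down", self.down)):
            ids = table["gene_id"]
            if symbols is None:
                out[f"{direction}_symbols"] = len(ids)
            else:
                out[f"{direction}_symbols"] = len({symbols.get(g, g) for g in ids})
        return out


def select_panel(records: pd.DataFrame, spec: PanelSpec) -> Panel:
    """Select the co-differential up and down gene lists for one panel.

    A gene qualifies for the up list when it is up in every comparison of
    the spec with minimum fold >= ``up_threshold`` (inclusive); the down
    list is analogous.  Lists are sorted by min_fold descending, gene id
    as tiebreak; per-comparison ratios are kept as columns for audit.
    """
    labels = [c.label for c in spec.comparisons]
    sub = records[records["pair"].isin(labels)]
    counts = sub.groupby("gene_id")["pair"].nunique()
    incomplete = counts[counts < len(labels)]
    if len(incomplete):
        raise PanelError(
            f"gene(s) missing comparisons for panel {spec.name!r}: "
            f"{sorted(incomplete.index)[:5]}"
        )
    ratios = sub.pivot(index="gene_id", columns="pair", values="ratio")[labels]
    dirs = sub.pivot(index="gene_id", columns="pair", values="direction")[labels]

    rows = []
    for gene_id in ratios.index:
        gene_dirs = set(dirs.loc[gene_id])
        if len(gene_dirs) != 1 or "flat" in gene_dirs:
            continue
        direction = gene_dirs.pop()
        fold = float(ratios.loc[gene_id].min())
        threshold = spec.up_threshold if direction == UP else spec.down_threshold
        if fold >= threshold:
            rows.append(
                {"gene_id": gene_id, "direction": direction, "min_fold": fold,
                 **{lab: float(ratios.at[gene_id, lab]) for lab in labels}}
            )
    columns = ["gene_id", "direction", "min_fold", *labels]
    table = pd.DataFrame(rows, columns=columns)
    table = table.sort_values(
        ["min_fold", "gene_id"], ascending=[False, True], ignore_index=True
    )
    return Panel(
        spec=spec,
        up=table[table["direction"] == UP].reset_index(drop=True),
        down=table[table["direction"] == DOWN].reset_index(drop=True),
    )
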