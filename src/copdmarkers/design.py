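"""Study design: the five sample groups and the ten comparison pairs.

The study contrasts peripheral blood mononuclear cell (PBMC) expression
across five groups: healthy controls (CON), stable COPD (STABLE), and
acute exacerbation of COPD sampled longitudinally at hospital days 1, 3
and 10 (AE1, AE3, AE10).  All differential analyses are performed over a
fixed set of ten group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUPS: tuple[str, ...] = ("CON", "STABLE", "AE1", "AE3", "AE10")

AE_GROUPS: tuple[str, ...] = ("AE1", "AE3", "AE10")

AE_DAYS: dict[str, int] = {"AE1": 1, "AE3": 3, "AE10": 10}


@dataclass(frozen=True, order=True)
class ComparisonPair:
    """A directed group comparison: numerator vs denominator."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        for g in (self.numerator, self.denominator):
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        if self.numerator == self.denominator:
            raise ValueError("comparison requires two distinct groups")

    @property
    def label(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"

    def swapped(self) -> "ComparisonPair":
        return ComparisonPair(self.denominator, self.numerator)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The ten comparison pairs of the study design.
TEN_PAIRS: tuple[ComparisonPair, ...] = (
    ComparisonPair("STABLE", "CON"),
    ComparisonPair("AE1", "CON"),
    ComparisonPair("AE3", "CON"),
    ComparisonPair("AE10", "CON"),
    ComparisonPair("AE1", "STABLE"),
    ComparisonPair("AE3", "STABLE"),
    ComparisonPair("AE10", "STABLE"),
    ComparisonPair("AE3", "AE1"),
    ComparisonPair("AE10", "AE1"),
    ComparisonPair("AE10", "AE3"),
)

#: The four "disease vs control" comparisons used for COPD-specific panels.
COPD_COMPARISONS: tuple[ComparisonPair, ...] = (
    ComparisonPair("STABLE", "CON"),
    ComparisonPair("AE1", "CON"),
    ComparisonPair("AE3", "CON"),
    ComparisonPair("AE10", "CON"),
)

#: The six "exacerbation vs baseline" comparisons used for AECOPD-specific
#: panels: each exacerbation day against both controls and stable COPD.
AECOPD_COMPARISONS: tuple[ComparisonPair, ...] = (
    ComparisonPair("AE1", "CON"),
    ComparisonPair("AE1", "STABLE"),
    ComparisonPair("AE3", "CON"),
    ComparisonPair("AE3", "STABLE"),
    ComparisonPair("AE10", "CON"),
    ComparisonPair("AE10", "STABLE"),
)

#: The two consecutive steps of the exacerbation time course.
TRAJECTORY_STEP1 = ComparisonPair("AE3", "AE1")
TRAJECTORY_STEP2 = ComparisonPair("AE10", "AE3")


class DesignError(ValueError):
    """Raised for an invalid sample sheet / study design."""


@dataclass
class StudyDesign:
    """Sample-to-(subject, group) assignment over the five study groups.

    Parameters
    ----------
    table:
        One row per sample with columns ``sample_id``, ``subject_id``,
        ``group`` and ``day`` (day is 0 for non-exacerbation groups).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "group", "day"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise DesignError(
                f"unknown group label(s) {sorted(bad)}; expected one of {GROUPS}"
            )
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise DesignError(f"duplicate sample id(s): {sorted(set(dupes))}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise DesignError(f"unknown group {group!r}")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def subjects_in(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "subject_id"])

    def missing_ae_days(self) -> dict[str, list[str]]:
        """AE subjects that lack one or more of the three sampling days."""
        ae = self.table[self.table["group"].isin(AE_GROUPS)]
        gaps: dict[str, list[str]] = {}
        for subject, sub in ae.groupby("subject_id"):
            absent = sorted(set(AE_GROUPS) - set(sub["group"]))
            if absent:
                gaps[str(subject)] = absent
        return gaps
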