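"""Digital Evaluation Score System (DESS) severity scoring.

DESS translates a patient's clinical state into one number: 64 clinical
components (symptoms and signs, biochemistry, imaging, other measures)
are each graded 0, 1, 2 or 4 — 0 within the normal physiological range,
4 far outside it — and the grades are summed, giving a total between 0
and 256 with higher meaning more severe.  The rubric mapping raw
measurements to component grades is external to this package; records
arrive already graded.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

VALID_LEVELS = frozenset({0, 1, 2, 4})
N_COMPONENTS = 64
MAX_TOTAL = 256  # 64 components x maximum grade 4

CATEGORIES = ("symptom_sign", "biochemistry", "imaging", "other")


class DessValidationError(ValueError):
    """Raised for a malformed DESS record or component."""


@dataclass(frozen=True)
class DessComponent:
    component_id: str
    category: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise DessValidationError(
                f"component {self.component_id!r}: level {self.level!r} "
                f"not in {sorted(VALID_LEVELS)} (3 is not a valid grade)"
            )
        if self.category not in CATEGORIES:
            raise DessValidationError(
                f"component {self.component_id!r}: unknown category "
                f"{self.category!r}"
            )


@dataclass(frozen=True)
class DessRecord:
    sample_id: str
    components: tuple[DessComponent, ...]

    def __post_init__(self) -> None:
        if len(self.components) != N_COMPONENTS:
            raise DessValidationError(
                f"record {self.sample_id!r}: expected {N_COMPONENTS} "
                f"components, got {len(self.components)}"
            )
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DessValidationError(
                f"record {self.sample_id!r}: duplicate component id(s) {dupes}"
            )


@dataclass(frozen=True)
class DessScore:
    sample_id: str
    total: int


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float  # NaN when n == 1

    def display(self) -> str:
        """``mean ± SE`` to one decimal, half-up, as printed in reports."""
        if self.n == 1:
            return f"{round_half_up(self.mean)} ± NA"
        return f"{round_half_up(self.mean)} ± {round_half_up(self.se)}"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), for display."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def score_record(record: DessRecord) -> DessScore:
    """Sum the 64 component grades into the record's DESS total."""
    return DessScore(record.sample_id, sum(c.level for c in record.components))


def summarize_group(
    scores: Iterable[DessScore | float | int], group: str = ""
) -> GroupSummary:
    """Mean and standard error of a group's DESS totals.

    SE is the n-1 sample standard deviation divided by sqrt(n); for a
    single score the SE is undefined and reported as NaN.
    """
    totals = np.array(
        [s.total if isinstance(s, DessScore) else float(s) for s in scores],
        dtype=float,
    )
    if totals.size == 0:
        raise DessValidationError("cannot summarize an empty score collection")
    mean = float(totals.mean())
    if totals.size == 1:
        return GroupSummary(group, 1, mean, float("nan"))
    se = float(totals.std(ddof=1) / np.sqrt(totals.size))
    return GroupSummary(group, int(totals.size), mean, se)


def severity_trajectory(means: Sequence[float]) -> str:
    """Two-step severity pattern over exacerbation days 1 -> 3 -> 10.

    Returns ``down-down``, ``down-up``, ``up-down`` or ``up-up``; any
    flat step yields ``flat-containing``.
    """
    if len(means) != 3:
        raise DessValidationError("severity trajectory needs exactly three means")
    steps = []
    for a, b in zip(means, means[1:]):
        if b > a:
            steps.append("up")
        elif b < a:
            steps.append("down")
        else:
            return "flat-containing"
    return "-".join(steps)


def record_from_levels(
    sample_id: str, levels: Sequence[int], categories: Sequence[str] | None = None
) -> DessRecord:
    """Build a record from 64 grades; ids c01..c64, categories cycled."""
    if categories is None:
        categories = [CATEGORIES[i % len(CATEGORIES)] for i in range(len(levels))]
    components = tuple(
        DessComponent(f"c{i + 1:02d}", cat, int(level))
        for i, (level, cat) in enumerate(zip(levels, categories))
    )
    return DessRecord(sample_id, components)
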