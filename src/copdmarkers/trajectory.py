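"""Dynamic two-step trajectory patterns over the exacerbation time course.

Each gene's expression across exacerbation days 1 -> 3 -> 10 is reduced
to a two-step direction pattern (down-down, down-up, up-down, up-up)
from the day-3-vs-day-1 and day-10-vs-day-3 fold changes.  A step with
ratio exactly 1 leaves the gene unclassified: the four patterns cover
strict movements only.  Pattern concordance with the clinical severity
(DESS) trajectory is the study's criterion for a dynamic biomarker.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign, TRAJECTORY_STEP1, TRAJECTORY_STEP2
from .diffexp import DOWN, UP, fold_change

PATTERNS = ("down-down", "down-up", "up-down", "up-up")
UNCLASSIFIED = "unclassified"

CALL_COLUMNS = (
    "gene_id", "step1_ratio", "step1_direction",
    "step2_ratio", "step2_direction", "pattern", "qualifying_fold",
)


def classify_steps(
    step1_ratio: float, step1_direction: str, step2_ratio: float, step2_direction: str
) -> tuple[str, float]:
    """Pattern label and qualifying fold from the two step records.

    The qualifying fold is the weaker (minimum) of the two step ratios;
    a flat step yields the unclassified label.
    """
    if step1_direction not in (UP, DOWN) or step2_direction not in (UP, DOWN):
        return UNCLASSIFIED, min(step1_ratio, step2_ratio)
    return f"{step1_direction}-{step2_direction}", min(step1_ratio, step2_ratio)


def classify(step1: pd.DataFrame, step2: pd.DataFrame) -> pd.DataFrame:
    """Trajectory calls for every gene from the two step record tables.

    ``step1`` / ``step2`` are long-format fold-change records for the
    day-3-vs-day-1 and day-10-vs-day-3 comparisons (same gene set).
    """
    s1 = step1.set_index("gene_id")
    s2 = step2.set_index("gene_id")
    common = s1.index.intersection(s2.index)
    rows = []
    for gene_id in common:
        pattern, fold = classify_steps(
            s1.at[gene_id, "ratio"], s1.at[gene_id, "direction"],
            s2.at[gene_id, "ratio"], s2.at[gene_id, "direction"],
        )
        rows.append(
            {
                "gene_id": gene_id,
                "step1_ratio": s1.at[gene_id, "ratio"],
                "step1_direction": s1.at[gene_id, "direction"],
                "step2_ratio": s2.at[gene_id, "ratio"],
                "step2_direction": s2.at[gene_id, "direction"],
                "pattern": pattern,
                "qualifying_fold": fold,
            }
        )
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


def classify_matrix(gene_matrix: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Convenience: compute both steps from a gene matrix, then classify."""
    return classify(
        fold_change(gene_matrix, design, TRAJECTORY_STEP1),
        fold_change(gene_matrix, design, TRAJECTORY_STEP2),
    )


def pattern_census(
    calls: pd.DataFrame, thresholds: Sequence[float] = (2.0,)
) -> pd.DataFrame:
    """Count classified genes per pattern with qualifying fold >= threshold.

    Returns a patterns x thresholds table; thresholds are inclusive.
    """
    out = {
        f">={t:g}": [
            int(
                (
                    (calls["pattern"] == pattern)
                    & (calls["qualifying_fold"] >= t)
                ).sum()
            )
            for pattern in PATTERNS
        ]
        for t in thresholds
    }
    return pd.DataFrame(out, index=pd.Index(PATTERNS, name="pattern"))


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between a gene's trajectory and the severity trajectory."""

    gene_id: str
    gene_pattern: str
    reference_pattern: str
    pattern_match: bool | None
    r: float


def _sign_pattern(values: Sequence[float]) -> str:
    steps = []
    for a, b in zip(values, values[1:]):
        if b > a:
            steps.append(UP)
        elif b < a:
            steps.append(DOWN)
        else:
            return UNCLASSIFIED
    return "-".join(steps)


def dess_concordance(
    gene_values: Sequence[float],
    dess_means: Sequence[float],
    gene_id: str = "",
    log_scale: bool = False,
) -> ConcordanceResult:
    """Compare a gene's signed stable-relative trajectory with DESS severity.

    ``gene_values`` are the gene's fold changes vs the stable-COPD group at
    exacerbation days 1, 3 and 10, signed (negative = below stable);
    ``dess_means`` are the three DESS group means on the same days.

    ``pattern_match`` is True when the two-step sign patterns of the two
    trajectories agree (defined only when the gene's pattern is strict).
    ``r`` is the Pearson correlation of the two 3-vectors — descriptive
    only (one degree of freedom); NaN when either vector has no variance.
    With ``log_scale`` the signed folds are mapped to sign * log2|fold|
    before correlating, which tempers the influence of very large folds.
    """
    g = np.asarray(gene_values, dtype=float)
    d = np.asarray(dess_means, dtype=float)
    if g.shape != (3,) or d.shape != (3,):
        raise ValueError("expected exactly three values per trajectory")
    gene_pattern = _sign_pattern(g)
    ref_pattern = _sign_pattern(d)
    match = None if gene_pattern == UNCLASSIFIED else (gene_pattern == ref_pattern)
    corr_g = np.sign(g) * np.log2(np.abs(g)) if log_scale else g
    if np.ptp(corr_g) == 0 or np.ptp(d) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(corr_g, d).statistic)
    return ConcordanceResult(gene_id, gene_pattern, ref_pattern, match, r)
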