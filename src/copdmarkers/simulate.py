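"""Seeded synthetic study generator with planted ground truth.

Emulates the five-group PBMC design — healthy controls, stable COPD and
exacerbation patients sampled longitudinally at days 1, 3 and 10 — at
the probe level, with known disease-specific, exacerbation-specific and
trajectory-pattern genes planted so that every downstream stage of the
pipeline can be tested against a recorded truth table.

Generative model (per probe p of gene g, sample s in group G):

    log2 intensity = baseline_g + probe_offset_p + effect_{g,G} + eps

with gene baselines N(baseline_log2_mean, baseline_log2_sd^2), fixed
per-probe offsets N(0, PROBE_OFFSET_SD^2) centred within each gene,
group effects of +/- log2(fold) in the comparisons a planted label
dictates, and i.i.d. residuals N(0, noise_sd^2).  Intensities are
exponentiated to the linear scale, so they are strictly positive.
Exacerbation samples at the three days share subject ids (the same
simulated individuals followed over time); control and stable arms are
independent subjects.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import AE_DAYS, AE_GROUPS, GROUPS, StudyDesign
from .dess import CATEGORIES, N_COMPONENTS

#: Spread of the fixed per-probe affinity offsets (log2 units).
PROBE_OFFSET_SD = 0.25

LABELS = (
    "copd_specific_up", "copd_specific_down",
    "aecopd_specific_up", "aecopd_specific_down",
    "traj_dd", "traj_du", "traj_ud", "traj_uu",
)

_TRAJ_STEPS = {  # label -> (day1, day3, day10) multipliers of log2(step fold)
    "traj_dd": (2.0, 1.0, 0.0),
    "traj_du": (1.0, 0.0, 1.0),
    "traj_ud": (0.0, 1.0, 0.0),
    "traj_uu": (0.0, 1.0, 2.0),
}


class SimulationError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedSpec:
    """How many genes to plant at which fold, and in which direction."""

    count: int
    fold: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise SimulationError("planted gene count must be >= 0")
        if self.fold <= 1:
            raise SimulationError(f"planted fold must be > 1, got {self.fold}")
        if self.direction not in ("up", "down"):
            raise SimulationError(f"direction must be up/down, got {self.direction!r}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Planted two-step dynamic pattern: label, gene count, per-step fold."""

    pattern: str
    count: int
    step_fold: float

    def __post_init__(self) -> None:
        if self.pattern not in _TRAJ_STEPS:
            raise SimulationError(
                f"pattern must be one of {sorted(_TRAJ_STEPS)}, got {self.pattern!r}"
            )
        if self.count < 0:
            raise SimulationError("planted gene count must be >= 0")
        if self.step_fold <= 1:
            raise SimulationError(f"step fold must be > 1, got {self.step_fold}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale and noise parameters of the synthetic design.

    Defaults mirror the emulated study: six subjects per arm, with
    log-normal intensity noise at a modest within-group residual.
    """

    seed: int
    n_subjects_per_arm: int = 6
    n_genes: int = 2000
    probes_per_gene: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    planted_copd: tuple[PlantedSpec, ...] = ()
    planted_aecopd: tuple[PlantedSpec, ...] = ()
    planted_trajectories: tuple[TrajectorySpec, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is required")
        if self.n_subjects_per_arm <= 0 or self.n_genes <= 0:
            raise SimulationError("subject and gene counts must be positive")
        if self.probes_per_gene < 1:
            raise SimulationError("probes_per_gene must be >= 1")
        if self.noise_sd < 0 or self.baseline_log2_sd < 0:
            raise SimulationError("standard deviations must be >= 0")
        total_planted = (
            sum(s.count for s in self.planted_copd)
            + sum(s.count for s in self.planted_aecopd)
            + sum(s.count for s in self.planted_trajectories)
        )
        if total_planted > self.n_genes:
            raise SimulationError(
                f"{total_planted} planted genes exceed n_genes={self.n_genes}"
            )


class SimulatedStudy(NamedTuple):
    probes: pd.DataFrame        # probes x samples, linear intensities
    design: StudyDesign
    annotation: pd.DataFrame    # probe_id -> gene_id
    truth: pd.DataFrame         # gene_id, label, fold


def _build_design(n: int) -> StudyDesign:
    rows = []
    for i in range(1, n + 1):
        rows.append((f"CON_s{i:02d}", f"con{i:02d}", "CON", 0))
    for i in range(1, n + 1):
        rows.append((f"STABLE_s{i:02d}", f"stb{i:02d}", "STABLE", 0))
    for group in AE_GROUPS:
        for i in range(1, n + 1):
            rows.append((f"{group}_s{i:02d}", f"ae{i:02d}", group, AE_DAYS[group]))
    return StudyDesign(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "group", "day"])
    )


def _group_effects(config: SimulationConfig, rng: np.random.Generator):
    """Assign planted labels to random genes; return per-gene group effects."""
    n = config.n_genes
    effects = np.zeros((n, len(GROUPS)))  # columns follow GROUPS order
    col = {g: j for j, g in enumerate(GROUPS)}
    labels = np.array(["null"] * n, dtype=object)
    folds = np.full(n, np.nan)

    specs: list[tuple[str, float]] = []
    for s in config.planted_copd:
        specs += [(f"copd_specific_{s.direction}", s.fold)] * s.count
    for s in config.planted_aecopd:
        specs += [(f"aecopd_specific_{s.direction}", s.fold)] * s.count
    for t in config.planted_trajectories:
        specs += [(t.pattern, t.step_fold)] * t.count

    chosen = rng.choice(n, size=len(specs), replace=False)
    for idx, (label, fold) in zip(chosen, specs):
        labels[idx] = label
        folds[idx] = fold
        shift = np.log2(fold)
        if label.startswith("copd_specific"):
            sign = 1.0 if label.endswith("up") else -1.0
            for g in ("STABLE", "AE1", "AE3", "AE10"):
                effects[idx, col[g]] = sign * shift
        elif label.startswith("aecopd_specific"):
            sign = 1.0 if label.endswith("up") else -1.0
            for g in AE_GROUPS:
                effects[idx, col[g]] = sign * shift
        else:  # trajectory pattern over the three exacerbation days
            d1, d3, d10 = _TRAJ_STEPS[label]
            effects[idx, col["AE1"]] = d1 * shift
            effects[idx, col["AE3"]] = d3 * shift
            effects[idx, col["AE10"]] = d10 * shift
    return effects, labels, folds


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a seeded probe matrix, design, annotation and truth table."""
    rng = np.random.default_rng(config.seed)
    design = _build_design(config.n_subjects_per_arm)
    n_samples = len(design.sample_ids)
    n_probes = config.n_genes * config.probes_per_gene

    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    probe_gene = np.repeat(np.arange(config.n_genes), config.probes_per_gene)
    probe_ids = [
        f"{gene_ids[g]}_p{p + 1}"
        for g in range(config.n_genes)
        for p in range(config.probes_per_gene)
    ]

    baselines = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    offsets = rng.normal(0.0, PROBE_OFFSET_SD, n_probes)
    if config.probes_per_gene > 1:  # centre offsets within each gene
        per_gene = offsets.reshape(config.n_genes, config.probes_per_gene)
        offsets = (per_gene - per_gene.mean(axis=1, keepdims=True)).ravel()
    else:
        offsets[:] = 0.0

    effects, labels, folds = _group_effects(config, rng)
    group_col = np.array([GROUPS.index(g) for g in design.table["group"]])

    log2_values = (
        baselines[probe_gene][:, None]
        + offsets[:, None]
        + effects[probe_gene][:, group_col]
    )
    if config.noise_sd > 0:
        log2_values = log2_values + rng.normal(
            0.0, config.noise_sd, (n_probes, n_samples)
        )

    probes = pd.DataFrame(
        np.exp2(log2_values),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=design.sample_ids,
    )
    annotation = pd.DataFrame(
        {"probe_id": probe_ids, "gene_id": [gene_ids[g] for g in probe_gene]}
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "label": labels, "fold": folds})
    return SimulatedStudy(probes, design, annotation, truth)


def generate_dess_records(
    design: StudyDesign,
    group_mean_targets: Mapping[str, float],
    dispersion: float,
    seed: int,
) -> pd.DataFrame:
    """Generate graded DESS records whose group means track the targets.

    Per sample, a target total is drawn as N(group target, dispersion^2),
    clipped to [0, 256]; components are then raised one grade at a time
    (0 -> 1 -> 2 -> 4) in random order until the running total reaches the
    sample's target.  Returns a long table with columns
    ``sample_id, component_id, category, level``.
    """
    for group, target in group_mean_targets.items():
        if not 0 <= target <= 256:
            raise SimulationError(
                f"group {group!r}: target {target} outside [0, 256]"
            )
    if dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    next_level = {0: 1, 1: 2, 2: 4}
    rows = []
    for _, sample in design.table.iterrows():
        target = group_mean_targets[sample["group"]]
        goal = float(np.clip(rng.normal(target, dispersion), 0, 256))
        levels = np.zeros(N_COMPONENTS, dtype=int)
        total = 0
        while total < goal - 0.5 and total < 256:
            open_idx = np.flatnonzero(levels < 4)
            j = int(rng.choice(open_idx))
            bump = next_level[levels[j]] - levels[j]
            levels[j] = next_level[levels[j]]
            total += bump
        for i, level in enumerate(levels):
            rows.append(
                (
                    sample["sample_id"],
                    f"c{i + 1:02d}",
                    CATEGORIES[i % len(CATEGORIES)],
                    int(level),
                )
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "component_id", "category", "level"]
    )


def realized_min_folds(
    gene_matrix: pd.DataFrame,
    design: StudyDesign,
    comparisons: Sequence,
) -> pd.Series:
    """Per-gene minimum realized fold over a comparison set (diagnostic)."""
    from .diffexp import fold_change

    ratios = pd.concat(
        [
            fold_change(gene_matrix, design, pair).set_index("gene_id")["ratio"]
            for pair in comparisons
        ],
        axis=1,
    )
    return ratios.min(axis=1)
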