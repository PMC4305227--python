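"""Tab-delimited readers/writers and the end-to-end pipeline runner.

All tables are plain TSV with '.' decimal separator; matrices carry a
header row of sample ids and a first column of probe/gene ids.  The
pipeline runner chains the stages (optional simulation, normalization,
differential expression, panel selection, trajectory classification,
DESS summaries, enrichment) and writes every stage output plus a JSON
run manifest that suffices to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .design import AE_GROUPS, GROUPS, DesignError, StudyDesign, TEN_PAIRS
from .dess import record_from_levels, score_record, summarize_group
from .diffexp import fold_change_table, threshold_census
from .enrichment import enrich_all, read_gmt
from .panels import aecopd_spec, copd_spec, select_panel
from .preprocess import log2_transform, quantile_normalize, summarize_probes
from .simulate import (
    PlantedSpec,
    SimulationConfig,
    generate_dess_records,
    generate_study,
)
from .trajectory import classify_matrix, pattern_census

log = logging.getLogger(__name__)

#: Default census fold thresholds (ascending), by direction.
UP_THRESHOLDS = (2, 5, 8, 10, 15, 20, 30, 50, 100)
DOWN_THRESHOLDS = (2, 5, 6, 8, 10, 15, 20, 30, 50, 100)


class TsvFormatError(ValueError):
    """Raised for malformed tab-delimited inputs, with file coordinates."""


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probes/genes x samples TSV matrix with full validation."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise TsvFormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        import numpy as np

        pos = int(np.flatnonzero(df.index.duplicated())[0])
        line = pos + 2  # header occupies line 1
        raise TsvFormatError(f"{path}:{line}: duplicate row id {df.index[pos]!r}")
    if df.columns.has_duplicates:
        dupe = df.columns[df.columns.duplicated()][0]
        raise TsvFormatError(f"{path}: duplicate sample id {dupe!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    missing = df.isna()
    for mask, what in ((bad, "non-numeric"), (missing, "missing")):
        if mask.any().any():
            i = mask.any(axis=1).idxmax()
            j = mask.loc[i].idxmax()
            line = list(df.index).index(i) + 2
            raise TsvFormatError(
                f"{path}:{line}: {what} value {df.loc[i, j]!r} in column {j!r}"
            )
    numeric.index.name = df.index.name or "id"
    return numeric


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "id")


def read_sample_sheet(path: str | Path) -> StudyDesign:
    """Read a sample sheet TSV into a validated study design.

    Requires columns sample_id, subject_id, group, day; groups must be
    one of the five study groups.  An exacerbation subject missing one of
    the three days is logged as a warning, not an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    try:
        design = StudyDesign(df)
    except DesignError as exc:
        raise TsvFormatError(f"{path}: {exc}") from exc
    for subject, missing in design.missing_ae_days().items():
        log.warning(
            "%s: exacerbation subject %s lacks day(s) %s", path, subject, missing
        )
    return design


def write_sample_sheet(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_dess_records(path: str | Path) -> pd.DataFrame:
    """Long-format DESS components: sample_id, component_id, category, level."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "component_id": str})
    required = {"sample_id", "component_id", "category", "level"}
    missing = required - set(df.columns)
    if missing:
        raise TsvFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def score_dess_table(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and score every sample of a long-format DESS table."""
    totals = []
    for sample_id, sub in records.groupby("sample_id", sort=False):
        record = record_from_levels(
            str(sample_id), list(sub["level"]), list(sub["category"])
        )
        totals.append((sample_id, score_record(record).total))
    return pd.DataFrame(totals, columns=["sample_id", "total"])


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    out_dir: Path
    seed: int = 0
    # either simulate ...
    simulate: bool = False
    n_genes: int = 2000
    n_subjects_per_arm: int = 6
    noise_sd: float = 0.25
    planted_aecopd_count: int = 50
    planted_aecopd_fold: float = 12.0
    # ... or load
    matrix_path: Path | None = None
    sample_sheet_path: Path | None = None
    annotation_path: Path | None = None
    gene_sets_path: Path | None = None
    dess_path: Path | None = None
    # thresholds
    up_thresholds: tuple = UP_THRESHOLDS
    down_thresholds: tuple = DOWN_THRESHOLDS
    copd_up: float = 10.0
    copd_down: float = 10.0
    aecopd_up: float = 10.0
    aecopd_down: float = 3.0
    trajectory_thresholds: tuple = (2, 4, 5)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("up_thresholds", "down_thresholds", "trajectory_thresholds"):
            values = list(getattr(self, name))
            if any(t < 1 for t in values) or values != sorted(values):
                raise ValueError(f"{name} must be >= 1 and ascending")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; write stage outputs and a run manifest.

    Returns a dict of in-memory stage results.  Deterministic given the
    seed: re-running with the same config yields byte-identical TSVs.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    # --- input ---------------------------------------------------------
    if config.simulate:
        info = stage("simulate")
        sim = generate_study(
            SimulationConfig(
                seed=config.seed,
                n_genes=config.n_genes,
                n_subjects_per_arm=config.n_subjects_per_arm,
                noise_sd=config.noise_sd,
                planted_aecopd=(
                    PlantedSpec(
                        config.planted_aecopd_count, config.planted_aecopd_fold
                    ),
                )
                if config.planted_aecopd_count
                else (),
            )
        )
        probes, design, annotation, truth = sim
        write_expression_tsv(probes, out / "probe_matrix.tsv")
        write_sample_sheet(design, out / "sample_sheet.tsv")
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        info["n_probes"] = int(probes.shape[0])
        results["truth"] = truth
    else:
        if config.matrix_path is None or config.sample_sheet_path is None:
            raise ValueError("matrix and sample sheet paths required unless simulating")
        probes = read_expression_tsv(config.matrix_path)
        design = read_sample_sheet(config.sample_sheet_path)
        if config.annotation_path is not None:
            annotation = pd.read_csv(config.annotation_path, sep="\t", dtype=str)
        else:  # one row per gene already
            annotation = pd.DataFrame(
                {"probe_id": probes.index, "gene_id": probes.index}
            )
    results["design"] = design

    # --- normalize -----------------------------------------------------
    info = stage("normalize")
    normalized = quantile_normalize(probes)
    genes = summarize_probes(
        log2_transform(normalized),
        dict(zip(annotation["probe_id"], annotation["gene_id"])),
    )
    write_expression_tsv(genes, out / "gene_matrix.tsv")
    info["n_genes"] = int(genes.shape[0])
    results["gene_matrix"] = genes

    # --- differential expression --------------------------------------
    info = stage("diffexp")
    records = fold_change_table(genes, design, TEN_PAIRS)
    records.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    for direction, thresholds in (
        ("up", config.up_thresholds),
        ("down", config.down_thresholds),
    ):
        census = threshold_census(records, direction, thresholds)
        census.to_csv(out / f"census_{direction}.tsv", sep="\t")
        results[f"census_{direction}"] = census
    info["n_records"] = int(len(records))
    info["n_comparisons"] = len(TEN_PAIRS)
    results["records"] = records

    # --- panels --------------------------------------------------------
    info = stage("panels")
    for spec in (
        copd_spec(config.copd_up, config.copd_down),
        aecopd_spec(config.aecopd_up, config.aecopd_down),
    ):
        panel = select_panel(records, spec)
        for direction, table in (("up", panel.up), ("down", panel.down)):
            table.to_csv(out / f"panel_{spec.name}_{direction}.tsv", sep="\t",
                         index=False)
        info[spec.name] = panel.symbol_counts()
        results[f"panel_{spec.name}"] = panel

    # --- trajectory ----------------------------------------------------
    info = stage("trajectory")
    calls = classify_matrix(genes, design)
    calls.to_csv(out / "trajectory_calls.tsv", sep="\t", index=False)
    census = pattern_census(calls, config.trajectory_thresholds)
    census.to_csv(out / "trajectory_census.tsv", sep="\t")
    info["patterns"] = {
        pattern: int(count) for pattern, count in census.iloc[:, 0].items()
    }
    results["trajectory_calls"] = calls
    results["trajectory_census"] = census

    # --- DESS ----------------------------------------------------------
    if config.dess_path is not None or config.simulate:
        info = stage("dess")
        if config.dess_path is not None:
            dess_records = read_dess_records(config.dess_path)
        else:
            dess_records = generate_dess_records(
                design,
                {"CON": 3.2, "STABLE": 38.7, "AE1": 85.7, "AE3": 70.5,
                 "AE10": 36.7},
                dispersion=5.0,
                seed=config.seed,
            )
            dess_records.to_csv(out / "dess_records.tsv", sep="\t", index=False)
        totals = score_dess_table(dess_records)
        totals = totals.merge(
            design.table[["sample_id", "group"]], on="sample_id", how="left"
        )
        summaries = []
        for group in GROUPS:
            group_totals = totals.loc[totals["group"] == group, "total"]
            if len(group_totals):
                s = summarize_group(group_totals, group)
                summaries.append((group, s.n, s.mean, s.se, s.display()))
        summary = pd.DataFrame(
            summaries, columns=["group", "n", "mean", "se", "display"]
        )
        totals.to_csv(out / "dess_totals.tsv", sep="\t", index=False)
        summary.to_csv(out / "dess_summary.tsv", sep="\t", index=False)
        info["groups"] = list(summary["group"])
        results["dess_summary"] = summary

    # --- enrichment ----------------------------------------------------
    if config.gene_sets_path is not None:
        info = stage("enrichment")
        path = Path(config.gene_sets_path)
        if not path.exists():
            raise FileNotFoundError(f"gene-set file not found: {path}")
        sets = read_gmt(str(path))
        universe = list(genes.index)
        panel = results["panel_aecopd_specific"]
        query = [g for g in panel.up["gene_id"] if g in set(universe)]
        if query:
            enrichment = enrich_all(query, sets, universe)
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enrichment
            info["n_sets_tested"] = int(len(enrichment))
        else:
            info["n_sets_tested"] = 0

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
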