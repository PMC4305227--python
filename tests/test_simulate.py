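"""Synthetic study generator: determinism, null behaviour, planted signal."""

import numpy as np
import pandas as pd
import pytest

from copdmarkers.design import (
    AECOPD_COMPARISONS,
    COPD_COMPARISONS,
    GROUPS,
    TEN_PAIRS,
)
from copdmarkers.diffexp import fold_change, fold_change_table
from copdmarkers.panels import aecopd_spec, select_panel
from copdmarkers.preprocess import log2_transform, summarize_probes
from copdmarkers.simulate import (
    PlantedSpec,
    SimulationConfig,
    SimulationError,
    TrajectorySpec,
    generate_dess_records,
    generate_study,
    realized_min_folds,
)

TARGETS = {"CON": 3.2, "STABLE": 38.7, "AE1": 85.7, "AE3": 70.5, "AE10": 36.7}


def summarize(sim):
    return summarize_probes(
        log2_transform(sim.probes),
        dict(zip(sim.annotation["probe_id"], sim.annotation["gene_id"])),
    )


class TestGenerateStudy:
    def test_shapes_and_longitudinal_subjects(self):
        config = SimulationConfig(seed=3, n_genes=20, probes_per_gene=3,
                                  n_subjects_per_arm=4)
        sim = generate_study(config)
        assert sim.probes.shape == (60, 20)
        assert (sim.probes.to_numpy() > 0).all()
        ae_subjects = [set(sim.design.subjects_in(g))
                       for g in ("AE1", "AE3", "AE10")]
        assert ae_subjects[0] == ae_subjects[1] == ae_subjects[2]
        assert not set(sim.design.subjects_in("CON")) & ae_subjects[0]

    def test_seeded_determinism_bit_identical(self):
        config = SimulationConfig(seed=7, n_genes=30, noise_sd=0.3,
                                  planted_copd=(PlantedSpec(3, 4.0),))
        a = generate_study(config)
        b = generate_study(config)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_null_noisefree_study_has_equal_group_means_everywhere(self):
        config = SimulationConfig(seed=5, n_genes=25, noise_sd=0.0)
        sim = generate_study(config)
        genes = summarize(sim)
        records = fold_change_table(genes, sim.design, TEN_PAIRS)
        assert np.allclose(records["ratio"], 1.0, atol=1e-9)
        panel = select_panel(
            records[records["pair"].isin(
                [c.label for c in AECOPD_COMPARISONS])],
            aecopd_spec(2, 2),
        )
        assert len(panel.up) == 0 and len(panel.down) == 0

    def test_signal_fidelity_at_zero_noise(self, noisefree_study):
        """Planted folds appear exactly in designated comparisons, nowhere else."""
        sim = noisefree_study
        genes = summarize(sim)
        records = fold_change_table(genes, sim.design, TEN_PAIRS)
        by_gene = records.set_index(["gene_id", "pair"])
        copd_labels = {c.label for c in COPD_COMPARISONS}
        for _, row in sim.truth[sim.truth["label"] != "null"].iterrows():
            for pair in TEN_PAIRS:
                ratio = by_gene.loc[(row["gene_id"], pair.label), "ratio"]
                if row["label"].startswith("copd"):
                    expected = row["fold"] if pair.label in copd_labels else 1.0
                elif row["label"].startswith("aecopd"):
                    in_set = pair.label in {c.label for c in AECOPD_COMPARISONS}
                    expected = row["fold"] if in_set else 1.0
                else:
                    continue
                assert ratio == pytest.approx(expected, abs=1e-9)

    def test_planted_direction_down_goes_below_control(self, noisefree_study):
        sim = noisefree_study
        genes = summarize(sim)
        down = sim.truth[sim.truth["label"] == "copd_specific_down"]
        rec = fold_change(genes, sim.design, COPD_COMPARISONS[0])
        sub = rec[rec["gene_id"].isin(down["gene_id"])]
        assert (sub["direction"] == "down").all()

    def test_realized_min_folds_concentrate_around_planted_value(self):
        """50 genes at 12-fold, noise 0.25: min fold in [8, 18] for >=95%."""
        config = SimulationConfig(
            seed=11, n_genes=2000, noise_sd=0.25, n_subjects_per_arm=6,
            planted_aecopd=(PlantedSpec(50, 12.0),),
        )
        sim = generate_study(config)
        genes = summarize(sim)
        planted = sim.truth.loc[
            sim.truth["label"] == "aecopd_specific_up", "gene_id"
        ]
        folds = realized_min_folds(genes, sim.design, AECOPD_COMPARISONS)
        inside = folds.loc[planted].between(8, 18).mean()
        assert inside >= 0.95

    def test_trajectory_planting_moves_only_exacerbation_days(self):
        config = SimulationConfig(
            seed=9, n_genes=30, noise_sd=0.0,
            planted_trajectories=(TrajectorySpec("traj_uu", 3, 3.0),),
        )
        sim = generate_study(config)
        genes = summarize(sim)
        planted = sim.truth.loc[sim.truth["label"] == "traj_uu", "gene_id"]
        from copdmarkers.trajectory import classify_matrix

        calls = classify_matrix(genes, sim.design).set_index("gene_id")
        assert (calls.loc[planted, "pattern"] == "up-up").all()
        assert calls.loc[planted, "qualifying_fold"].min() == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_subjects_per_arm": -1},
            {"probes_per_gene": 0},
            {"planted_copd": (PlantedSpec(3, 4.0),), "n_genes": 2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimulationConfig(seed=1, **{"n_genes": 10, **kwargs})

    def test_fold_at_or_below_one_rejected(self):
        with pytest.raises(SimulationError):
            PlantedSpec(3, 1.0)


class TestGenerateDess:
    def test_zero_target_zero_dispersion_all_zero(self, tiny_design):
        records = generate_dess_records(
            tiny_design, dict.fromkeys(GROUPS, 0.0), 0.0, seed=1
        )
        assert (records["level"] == 0).all()

    def test_saturated_target_fills_every_component(self, tiny_design):
        records = generate_dess_records(
            tiny_design, dict.fromkeys(GROUPS, 256.0), 0.0, seed=1
        )
        assert (records["level"] == 4).all()

    def test_group_means_track_reference_targets(self, tiny_design):
        records = generate_dess_records(tiny_design, TARGETS, 5.0, seed=17)
        totals = records.groupby("sample_id")["level"].sum()
        groups = tiny_design.table.set_index("sample_id")["group"]
        for group, target in TARGETS.items():
            realized = totals[groups == group].mean()
            assert abs(realized - target) <= 5.0

    def test_levels_are_valid_grades(self, tiny_design):
        records = generate_dess_records(tiny_design, TARGETS, 5.0, seed=2)
        assert set(records["level"]) <= {0, 1, 2, 4}
        per_sample = records.groupby("sample_id").size()
        assert (per_sample == 64).all()

    def test_target_out_of_range_rejected(self, tiny_design):
        with pytest.raises(SimulationError, match="outside"):
            generate_dess_records(
                tiny_design, dict.fromkeys(GROUPS, 300.0), 1.0, seed=1
            )
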