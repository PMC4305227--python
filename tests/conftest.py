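import numpy as np
import pandas as pd
import pytest

from copdmarkers import examples
from copdmarkers.design import StudyDesign
from copdmarkers.simulate import PlantedSpec, SimulationConfig, generate_study


@pytest.fixture(scope="session")
def copd_records():
    return examples.copd_panel_records()


@pytest.fixture(scope="session")
def aecopd_records():
    return examples.aecopd_panel_records()


@pytest.fixture(scope="session")
def noisefree_study():
    """Small noise-free study with planted genes of every kind."""
    config = SimulationConfig(
        seed=42,
        n_genes=60,
        probes_per_gene=2,
        noise_sd=0.0,
        baseline_log2_sd=1.0,
        planted_copd=(PlantedSpec(5, 6.0, "up"), PlantedSpec(3, 4.0, "down")),
        planted_aecopd=(PlantedSpec(4, 12.0, "up"),),
        planted_trajectories=(),
    )
    return generate_study(config)


@pytest.fixture
def tiny_design():
    """Two samples per group, fully enumerated."""
    rows = []
    for group in ("CON", "STABLE"):
        for i in (1, 2):
            rows.append((f"{group}{i}", f"{group.lower()}{i}", group, 0))
    for group, day in (("AE1", 1), ("AE3", 3), ("AE10", 10)):
        for i in (1, 2):
            rows.append((f"{group}_{i}", f"ae{i}", group, day))
    return StudyDesign(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "group", "day"])
    )


def make_gene_matrix(design, values_by_group, gene_ids=None):
    """Gene matrix whose samples all equal their group's stated log2 value."""
    data = {}
    for sample_id, group in zip(design.table["sample_id"], design.table["group"]):
        data[sample_id] = [v[group] for v in values_by_group]
    idx = gene_ids or [f"g{i}" for i in range(len(values_by_group))]
    return pd.DataFrame(data, index=pd.Index(idx, name="gene_id"), dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
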