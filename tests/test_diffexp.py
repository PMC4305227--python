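"""Fold-change computation, filtering and threshold censuses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from copdmarkers.design import ComparisonPair, TEN_PAIRS
from copdmarkers.diffexp import (
    DiffexpError,
    filter_genes,
    fold_change,
    fold_change_table,
    threshold_census,
)
from copdmarkers.preprocess import log2_transform, summarize_probes

from conftest import make_gene_matrix


def test_ten_comparison_pairs_enumerated():
    labels = {p.label for p in TEN_PAIRS}
    assert len(labels) == 10
    assert "AE1_vs_CON" in labels and "AE10_vs_AE3" in labels


def test_equal_group_means_give_flat_ratio_one(tiny_design):
    m = make_gene_matrix(tiny_design, [dict.fromkeys(
        ("CON", "STABLE", "AE1", "AE3", "AE10"), 5.0)])
    rec = fold_change(m, tiny_design, ComparisonPair("AE1", "CON"))
    assert rec.loc[0, "ratio"] == 1.0 and rec.loc[0, "direction"] == "flat"


def test_log2_difference_of_three_gives_eightfold_up(tiny_design):
    values = {"CON": 5.0, "STABLE": 5.0, "AE1": 8.0, "AE3": 5.0, "AE10": 5.0}
    m = make_gene_matrix(tiny_design, [values])
    rec = fold_change(m, tiny_design, ComparisonPair("AE1", "CON"))
    assert rec.loc[0, "ratio"] == pytest.approx(8.0)
    assert rec.loc[0, "direction"] == "up"


def test_noisefree_planted_fold_recovered_exactly(noisefree_study):
    """A gene planted at 12-fold shows ratio 12 in its designated pair."""
    probes, design, annotation, truth = noisefree_study
    genes = summarize_probes(
        log2_transform(probes),
        dict(zip(annotation["probe_id"], annotation["gene_id"])),
    )
    planted = truth[truth["label"] == "aecopd_specific_up"].iloc[0]
    rec = fold_change(genes, design, ComparisonPair("AE1", "CON"))
    row = rec[rec["gene_id"] == planted["gene_id"]].iloc[0]
    assert row["ratio"] == pytest.approx(12.0, abs=1e-9)
    assert row["direction"] == "up"


def test_empty_group_raises_naming_it(tiny_design):
    m = make_gene_matrix(tiny_design, [dict.fromkeys(
        ("CON", "STABLE", "AE1", "AE3", "AE10"), 5.0)])
    m = m.drop(columns=[c for c in m.columns if c.startswith("CON")])
    with pytest.raises(DiffexpError, match="CON"):
        fold_change(m, tiny_design, ComparisonPair("AE1", "CON"))


@settings(
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
@given(
    diffs=st.lists(
        st.floats(-6, 6, allow_nan=False), min_size=1, max_size=8
    )
)
def test_antisymmetry_swapping_groups_flips_direction(tiny_design, diffs):
    # tiny_design is read-only, so sharing it across generated inputs is safe
    values = [
        {"CON": 5.0, "STABLE": 5.0, "AE1": 5.0 + d, "AE3": 5.0, "AE10": 5.0}
        for d in diffs
    ]
    m = make_gene_matrix(tiny_design, values)
    pair = ComparisonPair("AE1", "CON")
    fwd = fold_change(m, tiny_design, pair)
    rev = fold_change(m, tiny_design, pair.swapped())
    assert np.allclose(fwd["ratio"], rev["ratio"])
    flips = {"up": "down", "down": "up", "flat": "flat"}
    assert list(rev["direction"]) == [flips[d] for d in fwd["direction"]]


def records_from_folds(folds, pair="AE1_vs_CON", direction="up"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(folds))],
            "pair": pair,
            "ratio": folds,
            "direction": direction,
        }
    )


class TestFilter:
    def test_threshold_is_inclusive_at_exactly_two(self):
        rec = records_from_folds([2.0, 1.9])
        assert filter_genes(rec, "AE1_vs_CON", "up", 2.0) == ["g0"]

    def test_threshold_one_keeps_all_nonflat_of_direction(self):
        rec = pd.concat(
            [records_from_folds([1.5, 3.0]),
             records_from_folds([1.0], direction="flat")],
            ignore_index=True,
        )
        assert len(filter_genes(rec, "AE1_vs_CON", "up", 1.0)) == 2

    def test_empty_records_give_empty_list(self):
        rec = records_from_folds([])
        assert filter_genes(rec, "AE1_vs_CON", "up", 2.0) == []

    def test_threshold_below_one_rejected(self):
        with pytest.raises(DiffexpError):
            filter_genes(records_from_folds([2.0]), "AE1_vs_CON", "up", 0.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        folds=st.lists(st.floats(1, 100), min_size=0, max_size=20),
        t1=st.floats(1, 50),
        t2=st.floats(1, 50),
    )
    def test_lower_threshold_selects_superset(self, folds, t1, t2):
        lo, hi = sorted((t1, t2))
        rec = records_from_folds(folds)
        assert set(filter_genes(rec, "AE1_vs_CON", "up", hi)) <= set(
            filter_genes(rec, "AE1_vs_CON", "up", lo)
        )


class TestCensus:
    def test_single_gene_at_twelvefold(self):
        rec = records_from_folds([12.0])
        census = threshold_census(
            rec, "up", [2, 5, 8, 10, 15], pairs=[ComparisonPair("AE1", "CON")]
        )
        assert list(census.loc["AE1_vs_CON"]) == [1, 1, 1, 1, 0]

    def test_thirty_planted_sixfold_genes(self):
        rec = records_from_folds([6.0] * 30)
        census = threshold_census(
            rec, "up", [2, 5, 8], pairs=[ComparisonPair("AE1", "CON")]
        )
        assert list(census.loc["AE1_vs_CON"]) == [30, 30, 0]

    def test_all_flat_matrix_counts_zero(self, tiny_design):
        m = make_gene_matrix(tiny_design, [dict.fromkeys(
            ("CON", "STABLE", "AE1", "AE3", "AE10"), 5.0)] * 4)
        rec = fold_change_table(m, tiny_design)
        census = threshold_census(rec, "up", [2, 5])
        assert (census.to_numpy() == 0).all()

    def test_counts_non_increasing_in_threshold(self, rng):
        rec = records_from_folds(rng.uniform(1, 40, 200))
        census = threshold_census(
            rec, "up", [2, 5, 8, 10, 15, 20, 30],
            pairs=[ComparisonPair("AE1", "CON")],
        )
        counts = census.loc["AE1_vs_CON"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(DiffexpError):
            threshold_census(records_from_folds([2.0]), "up", [5, 2])
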