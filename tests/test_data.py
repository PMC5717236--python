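"""The embedded catalogue, tidy-table IO and interaction-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from prefperf import (
    CommunityDataset,
    ValidationError,
    aggregate_survival,
    build_interaction_matrix,
    load_catalog,
    load_roster,
    validate_dataset,
)
from prefperf.data import (
    read_oviposition_table,
    read_survival_table,
    write_oviposition_table,
    write_survival_table,
)

from conftest import tiny_dataset


class TestCatalog:
    def test_catalogue_design_counts(self):
        cat = load_catalog()
        assert len(cat) == 29
        assert cat["family"].nunique() == 15
        assert cat["in_choice_subset"].sum() == 8
        assert list(cat["fruit_id"]) == list(range(1, 30))

    def test_choice_subset_is_the_starred_fruits(self):
        cat = load_catalog()
        chosen = set(cat.loc[cat["in_choice_subset"], "common_name"])
        assert chosen == {
            "Mango", "Indian almond", "Melon", "Pumpkin",
            "Strawberry guava", "Guava", "Chili", "Tomato",
        }

    def test_roster_guilds(self):
        roster = load_roster()
        assert len(roster) == 6
        assert (roster["guild"] == "specialist").sum() == 2
        assert (roster["guild"] == "generalist").sum() == 4


class TestTidyIO:
    def test_round_trip_preserves_records(self, tmp_path, default_dataset):
        p = tmp_path / "ovi.tsv"
        write_oviposition_table(default_dataset.oviposition, p)
        back = read_oviposition_table(p)
        pd.testing.assert_frame_equal(back, default_dataset.oviposition)
        p2 = tmp_path / "surv.tsv"
        write_survival_table(default_dataset.survival, p2)
        pd.testing.assert_frame_equal(read_survival_table(p2), default_dataset.survival)

    def test_dataset_dir_round_trip(self, tmp_path, default_dataset):
        default_dataset.to_dir(tmp_path)
        back = CommunityDataset.from_dir(tmp_path)
        pd.testing.assert_frame_equal(back.oviposition, default_dataset.oviposition)
        pd.testing.assert_frame_equal(back.survival, default_dataset.survival)
        pd.testing.assert_frame_equal(
            back.catalog, default_dataset.catalog.reset_index(drop=True)
        )

    def test_empty_table_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("species\tfruit_id\tassay\treplicate\tn_females\teggs\n")
        assert len(read_oviposition_table(p)) == 0

    def test_negative_eggs_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "species\tfruit_id\tassay\treplicate\tn_females\teggs\n"
            "Ceratitis capitata\t1\tno_choice\t1\t5\t3\n"
            "Ceratitis capitata\t2\tno_choice\t1\t5\t-1\n"
        )
        with pytest.raises(ValidationError, match="line 3.*negative"):
            read_oviposition_table(p)

    def test_unknown_species_and_fruit_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "species\tfruit_id\tassay\treplicate\tn_females\teggs\n"
            "Martian fly\t99\tno_choice\t1\t5\t3\n"
        )
        with pytest.raises(ValidationError, match="unknown"):
            read_oviposition_table(p, catalog=load_catalog(), roster=load_roster())

    def test_bad_pupated_value_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("species\tfruit_id\tcup\tpupated\nX\t1\t1\t2\n")
        with pytest.raises(ValidationError, match="pupated"):
            read_survival_table(p)


class TestSurvivalAggregation:
    @pytest.mark.parametrize(
        "n_cups,n_pupae,expected",
        [(30, 0, 0.0), (40, 40, 1.0), (50, 13, 0.26)],
    )
    def test_proportion_of_pupae(self, n_cups, n_pupae, expected):
        cups = [1] * n_pupae + [0] * (n_cups - n_pupae)
        ds = tiny_dataset({("a", 1): [1]}, {("a", 1): cups})
        cells = aggregate_survival(ds.survival)
        assert cells.loc[0, "n_trials"] == n_cups
        assert cells.loc[0, "survival"] == pytest.approx(expected)

    def test_zero_trial_cells_omitted(self):
        ds = tiny_dataset({("a", 1): [1], ("a", 2): [2]}, {("a", 1): [1, 0]})
        cells = aggregate_survival(ds.survival)
        assert set(zip(cells["species"], cells["fruit_id"])) == {("a", 1)}


class TestInteractionMatrix:
    def test_full_design_shape(self, default_dataset):
        m = build_interaction_matrix(default_dataset, "eggs")
        assert m.shape == (29, 6)
        m2 = build_interaction_matrix(default_dataset, "survival")
        assert m2.shape == (29, 6)
        assert not m2.missing_cells

    def test_single_record_single_cell(self):
        ds = tiny_dataset({("a", 2): [7]}, {("a", 1): [1]}, n_fruits=3)
        m = build_interaction_matrix(ds, "eggs")
        assert m.values.sum() == 7
        assert m.values[1, 0] == 7  # fruit 2, species a

    def test_mean_statistic(self):
        ds = tiny_dataset({("a", 1): [2, 4]}, {("a", 1): [1]})
        m = build_interaction_matrix(ds, "eggs", "mean")
        assert m.values[0, 0] == pytest.approx(3.0)

    def test_sum_equals_k_times_mean_with_balanced_replicates(self, default_dataset):
        s = build_interaction_matrix(default_dataset, "eggs", "sum")
        m = build_interaction_matrix(default_dataset, "eggs", "mean")
        k = default_dataset.oviposition.query("assay == 'no_choice'").groupby(
            ["species", "fruit_id"]
        ).size().iloc[0]
        np.testing.assert_allclose(s.values, k * m.values, rtol=1e-12)

    def test_missing_survival_cell_flagged_not_zeroed(self):
        ds = tiny_dataset(
            {("a", 1): [1], ("a", 2): [1]}, {("a", 1): [1, 0]}, n_fruits=2
        )
        m = build_interaction_matrix(ds, "survival")
        assert np.isnan(m.values[1, 0])
        assert ("a", 2) in m.missing_cells

    def test_empty_dataset_rejected(self):
        ds = tiny_dataset({("a", 1): [1]}, {("a", 1): [1]})
        ds.oviposition = ds.oviposition.iloc[:0]
        ds.survival = ds.survival.iloc[:0]
        with pytest.raises(ValidationError, match="empty"):
            build_interaction_matrix(ds, "eggs")

    def test_negative_values_rejected(self):
        from prefperf import InteractionMatrix

        with pytest.raises(ValueError, match="non-negative"):
            InteractionMatrix(np.array([[-1.0]]), [1], ["a"], "eggs")


class TestValidationReport:
    def test_missing_cells_enumerated(self):
        ds = tiny_dataset(
            {("a", 1): [1]}, {("a", 1): [1] * 30, ("b", 1): [0] * 30}, n_fruits=2
        )
        report = validate_dataset(ds)
        assert ("a", 2) in report["missing_oviposition_cells"]
        assert ("b", 1) in report["missing_oviposition_cells"]
        assert ("a", 2) in report["missing_survival_cells"]
        assert not report["unknown_species"]

    def test_cup_range_exceptions_logged(self):
        ds = tiny_dataset({("a", 1): [1]}, {("a", 1): [1] * 9})
        report = validate_dataset(ds)
        assert report["survival_cup_range_exceptions"] == {("a", 1): 9}

    def test_complete_default_design_is_clean(self, default_dataset):
        report = validate_dataset(default_dataset)
        assert not report["missing_oviposition_cells"]
        assert not report["missing_survival_cells"]
        assert not report["unknown_species"] and not report["unknown_fruits"]
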