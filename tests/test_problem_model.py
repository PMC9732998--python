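"""Criteria semantics, normalization, and the bundled hospital dataset."""

import numpy as np
import pandas as pd
import pytest

from fitsort import (
    ClassProfile,
    ConsequenceMatrix,
    Criterion,
    DegenerateCriterionError,
    MatrixParseError,
    compute_value_matrix,
    huol_criteria,
    load_consequence_matrix,
)


def make_matrix(data: dict, criteria, index=None):
    idx = index or [f"a{i}" for i in range(len(next(iter(data.values()))))]
    return ConsequenceMatrix(
        criteria=tuple(criteria),
        performance=pd.DataFrame(data, index=idx),
    )


class TestCriterion:
    def test_direction_aliases_normalize(self):
        assert Criterion("c", "min").direction == "minimize"
        assert Criterion("c", "Maximization").direction == "maximize"

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            Criterion("c", "sideways")

    @pytest.mark.parametrize(
        "direction,worst,best",
        [("maximize", 3, 1), ("minimize", 1, 3), ("maximize", 2, 2)],
    )
    def test_inconsistent_declared_levels_rejected(self, direction, worst, best):
        with pytest.raises(ValueError):
            Criterion("c", direction, worst_level=worst, best_level=best)


class TestClassProfile:
    def test_thresholds_must_increase_inside_unit_interval(self):
        with pytest.raises(ValueError):
            ClassProfile(thresholds=(0.7, 0.4))
        with pytest.raises(ValueError):
            ClassProfile(thresholds=(0.0, 0.7))

    def test_band_boundaries_are_upper_closed(self, profile):
        # a value exactly on a threshold belongs to the lower band
        assert profile.band_label(0.4) == "M"
        assert profile.band_label(0.7) == "B"
        assert profile.band_label(0.4 + 1e-12) == "M"  # within tolerance
        assert profile.band_label(0.41) == "B"
        assert profile.band_label(0.0) == "M"
        assert profile.band_label(1.0) == "W"


class TestLoadConsequenceMatrix:
    def test_bundled_dataset_loads(self, huol):
        assert huol.matrix.n_alternatives == 48
        assert huol.matrix.n_criteria == 5

    def test_duplicate_alternative_id_is_named(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "alternative,cost,demand,lead_time,criticality,volume\n"
            "x,1,2,3,1,0.5\nx,2,3,4,2,0.6\ny,1,1,1,3,0.1\n"
        )
        with pytest.raises(MatrixParseError, match="x"):
            load_consequence_matrix(p, huol_criteria())

    def test_out_of_range_built_scale_names_row_and_criterion(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "alternative,cost,demand,lead_time,criticality,volume\n"
            "x,1,2,3,4,0.5\ny,1,1,1,3,0.1\n"
        )
        with pytest.raises(MatrixParseError, match="criticality") as err:
            load_consequence_matrix(p, huol_criteria())
        assert "x" in str(err.value)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("alternative,cost,demand\nx,1,2\ny,2,3\n")
        with pytest.raises(MatrixParseError, match="lead_time"):
            load_consequence_matrix(p, huol_criteria())

    def test_non_numeric_cell_is_located(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "alternative,cost,demand,lead_time,criticality,volume\n"
            "x,1,2,3,1,0.5\ny,oops,1,1,3,0.1\n"
        )
        with pytest.raises(MatrixParseError, match="cost"):
            load_consequence_matrix(p, huol_criteria())

    def test_column_order_follows_criteria_config_not_file(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "alternative,volume,cost,criticality,lead_time,demand\n"
            "x,0.5,1,1,3,2\ny,0.1,2,3,1,9\n"
        )
        m = load_consequence_matrix(p, huol_criteria())
        assert list(m.performance.columns) == [c.name for c in huol_criteria()]

    def test_round_trip_is_exact(self, huol, tmp_path):
        p = tmp_path / "rt.csv"
        huol.matrix.to_csv(p)
        again = load_consequence_matrix(p, huol_criteria())
        pd.testing.assert_frame_equal(again.performance, huol.matrix.performance)


class TestComputeValueMatrix:
    def test_built_scale_best_level_maps_to_one(self):
        m = make_matrix(
            {"crit": [1, 2, 3], "cost": [5.0, 1.0, 2.0]},
            [
                Criterion("crit", "maximize", scale_kind="built",
                          worst_level=1, best_level=3),
                Criterion("cost", "minimize"),
            ],
        )
        v = compute_value_matrix(m)
        assert v.values["crit"].tolist() == [0.0, 0.5, 1.0]

    def test_minimized_criterion_worst_observed_maps_to_zero(self, huol, huol_values):
        lead = huol.matrix.performance["lead_time"]
        worst = lead.idxmax()
        best = lead.idxmin()
        assert lead.max() == 57
        assert huol_values.values.loc[worst, "lead_time"] == 0.0
        assert huol_values.values.loc[best, "lead_time"] == 1.0

    def test_midpoint_of_observed_range_maps_to_half(self):
        lo, hi = 26.0, 43391.0
        m = make_matrix(
            {"demand": [lo, (lo + hi) / 2, hi], "cost": [1.0, 2.0, 3.0]},
            [Criterion("demand", "maximize"), Criterion("cost", "minimize")],
        )
        v = compute_value_matrix(m)
        assert v.values["demand"].tolist() == [0.0, 0.5, 1.0]

    def test_every_huol_criterion_attains_both_endpoints(self, huol_values):
        assert (huol_values.values.max() == 1.0).all()
        assert (huol_values.values.min() == 0.0).all()

    def test_idempotent_and_scale_equivariant(self, huol):
        v1 = compute_value_matrix(huol.matrix)
        v2 = compute_value_matrix(huol.matrix)
        pd.testing.assert_frame_equal(v1.values, v2.values)
        # positive affine rescale of a raw column leaves values unchanged
        perf = huol.matrix.performance.copy()
        perf["cost"] = 3.7 * perf["cost"] + 12.0
        rescaled = ConsequenceMatrix(huol.matrix.criteria, perf)
        v3 = compute_value_matrix(rescaled)
        np.testing.assert_allclose(
            v3.values["cost"], v1.values["cost"], atol=1e-12
        )

    def test_declared_levels_clip_out_of_range_values(self):
        m = make_matrix(
            {"d": [5.0, 50.0, 150.0], "cost": [1.0, 2.0, 3.0]},
            [
                Criterion("d", "maximize", worst_level=10, best_level=100),
                Criterion("cost", "minimize"),
            ],
        )
        v = compute_value_matrix(m)
        assert v.values["d"].tolist() == [0.0, pytest.approx(4 / 9), 1.0]

    def test_degenerate_criterion_rejected_with_guidance(self):
        m = make_matrix(
            {"flat": [2.0, 2.0, 2.0], "cost": [1.0, 2.0, 3.0]},
            [Criterion("flat", "maximize"), Criterion("cost", "minimize")],
        )
        with pytest.raises(DegenerateCriterionError, match="declare levels"):
            compute_value_matrix(m)


class TestHUOLFixture:
    def test_first_row_matches_published_values(self, huol):
        row = huol.matrix.performance.loc["Alteplase, 50 mg, lyophylic powder"]
        assert row["cost"] == 2022.99
        assert row["demand"] == 5
        assert row["lead_time"] == 13
        assert row["criticality"] == 3
        assert row["volume"] == 0.0004233

    def test_profile_and_ranking(self, huol):
        assert huol.profile.thresholds == (0.4, 0.7)
        assert huol.profile.labels == ("M", "B", "W")
        assert huol.ranking == ("demand", "criticality", "lead_time", "cost", "volume")

    def test_reference_bounds_cover_all_48_items(self, ref_bounds, huol):
        assert len(ref_bounds) == 48
        assert set(ref_bounds.index) == set(huol.matrix.alternatives)
        assert (ref_bounds["s1"] <= ref_bounds["s2"]).all()

    def test_reference_bounds_spot_values(self, ref_bounds):
        mask = ref_bounds.loc["Rectangular surgical mask with strips - 3 layers"]
        assert mask["s1"] == 0.87555622
        assert mask["s2"] == 1.0
        assert mask["classes"] == "W"
        needle = ref_bounds.loc["Myelogram aspiration needle 16 g - 6 cm to 7 cm"]
        assert needle["s1"] == 0.20994426
        assert needle["s2"] == 0.45862365
        assert needle["classes"] == "B|M"
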