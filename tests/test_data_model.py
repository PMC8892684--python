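"""Treatment-mean database: I/O, validation, derived fields, summaries."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from ruminergy import (
    EnergyDatabase,
    TreatmentMean,
    describe,
    derived_fields,
    median_split_summary,
    read_database,
    validate,
    with_derived,
    write_database,
)


class TestReadDatabase:
    def test_fixture_has_47_rows_from_11_studies(self, table1):
        assert len(table1) == 47
        assert len(table1.studies()) == 11

    def test_zilpaterol_study_control_row(self, table1):
        f = table1.frame
        row = f[(f["citation_id"] == "study_44") & (f["diet_label"] == "Control")].iloc[0]
        assert row["de"] == 3.81
        assert row["me"] == 3.69
        assert row["ch4_pct_de"] == 2.5
        assert row["me_de_ratio"] == 0.9685

    def test_empty_data_section_gives_empty_database(self):
        db = read_database(io.StringIO("citation_id,diet_label,de,me\n"), dialect="csv")
        assert len(db) == 0

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("diet_label,de,me\na,3.0,2.6\n")
        with pytest.raises(ValueError, match="citation_id"):
            read_database(p)

    def test_missing_cells_become_nan_not_zero(self):
        db = read_database(
            io.StringIO("citation_id,diet_label,de,me\ns1,a,3.0,\n"), dialect="csv"
        )
        assert math.isnan(db.frame.loc[0, "me"])

    def test_header_aliases_and_column_map(self):
        text = "Source,Diet,DE,ME\ns1,a,3.0,2.6\n"
        db = read_database(io.StringIO(text), dialect="csv")
        assert db.frame.loc[0, "citation_id"] == "s1"
        assert db.frame.loc[0, "de"] == 3.0
        db2 = read_database(
            io.StringIO("Study code,Diet,DE,ME\ns1,a,3.0,2.6\n"),
            dialect="csv",
            column_map={"Study code": "citation_id"},
        )
        assert db2.frame.loc[0, "citation_id"] == "s1"

    def test_round_trip_preserves_fields(self, table1, tmp_path):
        out = tmp_path / "rt.csv"
        write_database(table1, out)
        back = read_database(out)
        pd.testing.assert_frame_equal(
            table1.frame[back.frame.columns], back.frame, check_dtype=False
        )

    def test_duplicate_treatment_keys_rejected(self):
        rows = [TreatmentMean("s1", "a", de=3.0), TreatmentMean("s1", "a", de=3.1)]
        with pytest.raises(ValueError, match="duplicate"):
            EnergyDatabase.from_rows(rows)


class TestValidate:
    def test_fixture_is_clean_at_default_tolerance(self, table1):
        assert validate(table1, ratio_tol=0.005).empty

    def test_me_exceeding_de_is_flagged(self):
        db = EnergyDatabase.from_rows([TreatmentMean("s1", "a", de=2.9, me=3.0)])
        codes = [i.issue_code for i in validate(db).issues]
        assert "ME_EXCEEDS_DE" in codes

    def test_printed_ratio_within_rounding_tolerance_passes(self):
        # 3.42 / 3.73 = 0.91689 vs printed 0.9173: inside the 0.005 band
        db = EnergyDatabase.from_rows(
            [TreatmentMean("s1", "a", de=3.73, me=3.42, me_de_ratio=0.9173)]
        )
        assert validate(db, ratio_tol=0.005).empty

    def test_ratio_mismatch_beyond_tolerance_flagged(self):
        db = EnergyDatabase.from_rows(
            [TreatmentMean("s1", "a", de=3.0, me=2.6, me_de_ratio=0.95)]
        )
        codes = [i.issue_code for i in validate(db).issues]
        assert "RATIO_MISMATCH" in codes

    def test_reports_do_not_raise_on_bad_rows(self):
        db = EnergyDatabase.from_rows(
            [TreatmentMean("s1", "a", de=2.0, me=3.0, ge=1.0, bw=-5, ch4_pct_de=150)]
        )
        report = validate(db)
        assert len(report.errors()) >= 3


class TestDerivedFields:
    @pytest.mark.parametrize(
        "row, field, expected",
        [
            (TreatmentMean("s", ch4_pct_de=7.5, de=3.21), "ch4_mcal_per_kg_dm", 0.24075),
            (TreatmentMean("s", ch4_pct_de=0.0, de=3.21), "ch4_mcal_per_kg_dm", 0.0),
            (TreatmentMean("s", dmi=4.58, bw=432), "dmi_pct_bw", 1.060185185),
            (TreatmentMean("s", ge=4.21, dmi=4.58), "ge_intake_mcal_d", 19.2818),
            (TreatmentMean("s", urine_pct_de=6.1, de=3.21), "urine_mcal_per_kg_dm", 0.195810),
        ],
    )
    def test_hand_computed_values(self, row, field, expected):
        assert derived_fields(row)[field] == pytest.approx(expected, rel=1e-9)

    def test_missing_input_gives_missing_output_only_for_that_field(self):
        out = derived_fields(TreatmentMean("s", de=3.0, me=2.6))
        assert out["me_de_ratio_calc"] == pytest.approx(2.6 / 3.0)
        assert out["dmi_pct_bw"] is None
        assert out["ch4_mcal_per_kg_dm"] is None

    def test_printed_ratios_agree_with_computed_on_every_fixture_row(self, table1_derived):
        diff = (table1_derived["me_de_ratio"] - table1_derived["me_de_ratio_calc"]).abs()
        assert float(diff.max()) <= 0.005


class TestDescribe:
    def test_counts_on_fixture(self, table1):
        t = describe(table1)
        assert t.loc["de", "count"] == 47
        assert t.loc["me", "count"] == 47

    def test_sd_uses_sample_denominator(self, table1):
        t = describe(table1, variables=["de"])
        f = table1.frame
        assert t.loc["de", "sd"] == pytest.approx(f["de"].std(ddof=1))

    def test_single_row_mean_is_value_sd_missing(self):
        db = EnergyDatabase.from_rows([TreatmentMean("s1", "a", de=3.0, me=2.6)])
        t = describe(db, variables=["de"])
        assert t.loc["de", "mean"] == 3.0
        assert math.isnan(t.loc["de", "sd"])

    def test_entirely_missing_variable_omitted_with_warning(self):
        db = EnergyDatabase.from_rows([TreatmentMean("s1", "a", de=3.0, me=2.6)])
        with pytest.warns(UserWarning, match="bw"):
            t = describe(db, variables=["de", "bw"])
        assert "bw" not in t.index


class TestMedianSplit:
    def test_enumeration_four_rows(self):
        rows = [TreatmentMean(f"s{i}", "a", de=v, me=v - 0.4) for i, v in enumerate([4.0, 3.0, 2.0, 1.0], 1)]
        db = EnergyDatabase.from_rows(rows)
        t = median_split_summary(db, sort_var="de", summary_vars=["de"])
        assert t.loc["top", "de"] == pytest.approx(3.5)
        assert t.loc["bottom", "de"] == pytest.approx(1.5)

    def test_identical_rows_give_equal_group_means(self):
        rows = [TreatmentMean(f"s{i}", "a", de=3.0, me=2.6, ndf=30.0) for i in range(4)]
        db = EnergyDatabase.from_rows(rows)
        t = median_split_summary(db, sort_var="de", summary_vars=["ndf"])
        assert t.loc["top", "ndf"] == t.loc["bottom", "ndf"] == 30.0

    def test_group_sizes_differ_by_at_most_one_and_sum_to_n(self, table1):
        t = median_split_summary(table1)
        assert t["n"].sum() == len(table1)
        assert abs(t.loc["top", "n"] - t.loc["bottom", "n"]) <= 1

    def test_fewer_than_two_rows_errors(self):
        db = EnergyDatabase.from_rows([TreatmentMean("s1", "a", de=3.0, me=2.6)])
        with pytest.raises(ValueError):
            median_split_summary(db, sort_var="de", summary_vars=["de"])

    def test_sort_var_not_computable_errors(self, table1):
        frame = table1.frame.copy()
        frame.loc[0, "ch4_pct_de"] = np.nan
        with pytest.raises(ValueError, match="computable"):
            median_split_summary(EnergyDatabase(frame), "ch4_mcal_per_kg_dm", ["ndf"])
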