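"""Descriptive frequency tables, rounding, and time-to-onset binning."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv import descriptives as de
from faerspv.descriptives import (
    assign_tto_bin,
    annual_counts,
    compute_tto,
    frequency_table,
    indication_table,
    percent,
    round_half_up,
    stratified_signals,
    tto_table,
)


@pytest.mark.parametrize(
    "x,dec,expected",
    [
        (36.015037, 2, 36.02),   # half-up at the third decimal
        (44.885, 2, 44.89),
        (67.36799, 1, 67.4),
        (21.6145, 1, 21.6),
        (0.05, 1, 0.1),
        (2.25, 1, 2.3),          # half-up, not banker's rounding
    ],
)
def test_round_half_up(x, dec, expected):
    assert round_half_up(x, dec) == expected


def _cases(rows):
    df = pd.DataFrame(
        rows,
        columns=["primaryid", "fda_dt", "sex", "age_group",
                 "reporter_country", "occp_cod", "outcomes"],
    )
    df["event_dt"] = pd.NA
    return df


class TestFrequencyTables:
    def test_annual_counts_example(self):
        cases = _cases([
            ("1", "20200101", "F", "65–85", "US", "MD", frozenset()),
            ("2", "20200601", "F", "65–85", "US", "MD", frozenset()),
            ("3", "20210101", "M", "18–64", "JP", "CN", frozenset()),
        ])
        ft = annual_counts(cases, {"1", "2", "3"})
        got = dict(zip(ft.rows["category"], zip(ft.rows["count"], ft.rows["percent"])))
        assert got == {"2020": (2, 66.7), "2021": (1, 33.3)}

    def test_empty_cohort_empty_table(self):
        ft = annual_counts(_cases([]), set())
        assert ft.rows.empty and ft.denominator == 0

    def test_sex_with_explicit_missing(self):
        cases = _cases([
            ("1", "20200101", "F", "65–85", "US", "MD", frozenset()),
            ("2", "20200101", "Missing", "65–85", "US", "MD", frozenset()),
        ])
        ft = frequency_table(cases, {"1", "2"}, "sex")
        assert list(ft.rows["category"]) == ["Female", de.MISSING_LABEL]
        assert ft.rows["count"].sum() == ft.denominator

    def test_outcome_set_semantics_multi_membership(self):
        cases = _cases([
            ("1", "20200101", "F", "65–85", "US", "MD", frozenset({"HO", "DE"})),
            ("2", "20200101", "F", "65–85", "US", "MD", frozenset({"OT", "RI"})),
        ])
        ft = frequency_table(cases, {"1", "2"}, "outcome")
        got = dict(zip(ft.rows["category"], ft.rows["count"]))
        assert got["Hospitalization"] == 1 and got["Death"] == 1
        # OT and RI merge into one row counted once for report 2
        assert got["Other serious / required intervention"] == 1
        assert ft.multi_membership

    def test_occupation_mapping(self):
        cases = _cases([
            ("1", "20200101", "F", "65–85", "US", "MD", frozenset()),
            ("2", "20200101", "F", "65–85", "US", "OT", frozenset()),
            ("3", "20200101", "F", "65–85", "US", pd.NA, frozenset()),
        ])
        ft = frequency_table(cases, {"1", "2", "3"}, "reporting_source")
        got = dict(zip(ft.rows["category"], ft.rows["count"]))
        assert got == {"Physician": 1, "Health professional": 1,
                       "Missing / not specified": 1}

    def test_country_floor_collapses_small_rows(self):
        rows = [(str(i), "20200101", "F", "65–85", "US", "MD", frozenset())
                for i in range(98)]
        rows += [("98", "20200101", "F", "65–85", "FJ", "MD", frozenset()),
                 ("99", "20200101", "F", "65–85", "TV", "MD", frozenset())]
        ft = frequency_table(_cases(rows), {str(i) for i in range(100)}, "country",
                             country_floor_pct=1.5)
        got = dict(zip(ft.rows["category"], ft.rows["count"]))
        assert got == {"US": 98, "All other countries": 2}

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            frequency_table(_cases([]), set(), "shoe_size")

    def test_counts_sum_to_denominator_and_percents_to_100(self, small_sim):
        from faerspv import cleaning, faers_io
        cfg, files, truth = small_sim
        demo = faers_io.concat_quarters(
            [faers_io.parse_faers_table(t, "demo")
             for n, t in sorted(files.items()) if n.startswith("DEMO")]
        )
        retained = cleaning.deduplicate_cases(demo)
        cases = cleaning.build_report_cases(demo, retained)
        for dim in ("sex", "age_group", "country"):
            ft = frequency_table(cases, retained, dim)
            assert ft.rows["count"].sum() == ft.denominator
            assert ft.rows["percent"].sum() == pytest.approx(100, abs=0.3)


class TestIndications:
    DRUG = pd.DataFrame(
        {
            "primaryid": ["1", "1", "2", "3", "4"],
            "drug_seq": ["1", "2", "1", "1", "1"],
            "role_cod": ["PS", "C", "PS", "PS", "PS"],
            "drugname": ["X"] * 5,
        },
        dtype="string",
    )

    def test_grouping_and_linkage(self):
        indi = pd.DataFrame(
            {
                "primaryid": ["1", "1", "2", "3", "4"],
                "indi_drug_seq": ["1", "2", "1", "1", "1"],
                "indi_pt": ["OSTEOPOROSIS POSTMENOPAUSAL", "IGNORED NON-PS",
                            "OSTEOPOROSIS", "SENILE OSTEOPOROSIS", "BONE METASTASES"],
            },
            dtype="string",
        )
        grouping = {k: "Osteoporosis-related"
                    for k in ("OSTEOPOROSIS", "OSTEOPOROSIS POSTMENOPAUSAL",
                              "SENILE OSTEOPOROSIS")}
        ft = indication_table(indi, self.DRUG, {"1", "2", "3", "4"}, grouping)
        got = dict(zip(ft.rows["category"], ft.rows["percent"]))
        # the non-PS row is excluded; 3 of 4 reports group → 75%
        assert got["Osteoporosis-related"] == 75.0
        assert got["BONE METASTASES"] == 25.0


class TestTTO:
    @pytest.mark.parametrize(
        "days,bin_", [(0, "0–30"), (30, "0–30"), (31, "31–60"), (60, "31–60"),
                      (90, "61–90"), (120, "91–120"), (150, "121–150"),
                      (180, "151–180"), (360, "181–360"), (361, ">360"),
                      (10000, ">360")],
    )
    def test_bin_edges(self, days, bin_):
        assert assign_tto_bin(days) == bin_

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=100000))
    def test_binning_total(self, days):
        assert assign_tto_bin(days) in de.TTO_BINS

    def _fixture(self, event_dt, start_dt):
        cases = pd.DataFrame(
            {"primaryid": ["1"], "event_dt": [event_dt]}, dtype="string"
        )
        ther = pd.DataFrame(
            {"primaryid": ["1"], "dsg_drug_seq": ["1"], "start_dt": [start_dt]},
            dtype="string",
        )
        drug = pd.DataFrame(
            {"primaryid": ["1"], "drug_seq": ["1"], "role_cod": ["PS"],
             "drugname": ["X"]},
            dtype="string",
        )
        return cases, ther, drug

    def test_thirty_days_inclusive_edge(self):
        tto, _ = compute_tto(*self._fixture("20200131", "20200101"), {"1"})
        assert tto.iloc[0]["tto_days"] == 30 and tto.iloc[0]["bin"] == "0–30"

    def test_long_onset(self):
        tto, _ = compute_tto(*self._fixture("20210102", "20200101"), {"1"})
        assert tto.iloc[0]["tto_days"] == 367 and tto.iloc[0]["bin"] == ">360"

    def test_negative_interval_excluded_and_logged(self):
        tto, log = compute_tto(*self._fixture("20200215", "20200301"), {"1"})
        assert tto.empty and log["negative_tto"] == 1

    def test_partial_dates_excluded_and_logged(self):
        tto, log = compute_tto(*self._fixture("202001", "20200101"), {"1"})
        assert tto.empty and log["partial_or_missing_dates"] == 1

    def test_earliest_linked_start_wins(self):
        cases = pd.DataFrame({"primaryid": ["1"], "event_dt": ["20200301"]}, dtype="string")
        ther = pd.DataFrame(
            {"primaryid": ["1", "1"], "dsg_drug_seq": ["1", "1"],
             "start_dt": ["20200201", "20200101"]},
            dtype="string",
        )
        drug = pd.DataFrame(
            {"primaryid": ["1"], "drug_seq": ["1"], "role_cod": ["PS"],
             "drugname": ["X"]},
            dtype="string",
        )
        tto, _ = compute_tto(cases, ther, drug, {"1"})
        assert tto.iloc[0]["tto_days"] == 60

    def test_table_percents_two_decimals(self):
        recs = pd.DataFrame({"primaryid": ["1", "2", "3"],
                             "tto_days": [5, 10, 400],
                             "bin": ["0–30", "0–30", ">360"]})
        ft = tto_table(recs)
        got = dict(zip(ft.rows["category"], ft.rows["percent"]))
        assert got == {"0–30": 66.67, ">360": 33.33}

    def test_single_bin_is_100(self):
        recs = pd.DataFrame({"primaryid": ["1"], "tto_days": [5], "bin": ["0–30"]})
        assert tto_table(recs).rows.iloc[0]["percent"] == 100.0

    def test_empty_input_empty_table(self):
        assert tto_table(pd.DataFrame(columns=["primaryid", "tto_days", "bin"])).rows.empty


def test_small_stratum_skipped_with_warning():
    reac = pd.DataFrame({"primaryid": [str(i) for i in range(10)], "pt": ["X"] * 10})
    with pytest.warns(UserWarning, match="skipped"):
        out = stratified_signals(
            {"1"}, reac, {str(i) for i in range(10)},
            {"tiny": {str(i) for i in range(10)}}, min_reports=50,
        )
    assert out == {}
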