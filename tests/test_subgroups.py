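"""Descriptive characterisation and the suicide-vs-other contingency tests.

The three demographic contingency tables published for the vortioxetine
suicide cohort serve as fixed inputs with known uncorrected Pearson
chi-square values (48.77 sex, 30.17 age, 0.88 weight).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pvsignal import ValidationError
from pvsignal.constants import SUICIDE_PTS
from pvsignal.ingest import Cohort, IngestReport
from pvsignal.subgroups import (
    MISSING,
    age_rebin,
    characterize,
    label_suicide_reports,
    proportion_pct,
    subgroup_test,
    suicide_subgroup_tables,
    weight_rebin,
)

SEX_TABLE = [[7624, 708], [3180, 459]]
AGE_TABLE = [[982, 109], [4102, 570], [965, 75], [86, 2]]
WEIGHT_TABLE = [[157, 14], [1967, 202], [340, 40]]


class TestSubgroupTest:
    def test_sex_table_chi2(self):
        res = subgroup_test(SEX_TABLE, policy="pearson")
        assert res.chi2 == pytest.approx(48.77, abs=0.01)
        assert res.p_value < 0.001
        assert res.df == 1

    def test_age_table_chi2(self):
        res = subgroup_test(AGE_TABLE, policy="pearson")
        assert res.chi2 == pytest.approx(30.17, abs=0.01)
        assert res.p_value < 0.001
        assert res.df == 3

    def test_weight_table_chi2_and_p(self):
        res = subgroup_test(WEIGHT_TABLE, policy="pearson")
        assert res.chi2 == pytest.approx(0.88, abs=0.01)
        assert res.p_value == pytest.approx(0.64, abs=0.01)

    def test_auto_policy_keeps_pearson_for_printed_tables(self):
        for table in (SEX_TABLE, AGE_TABLE, WEIGHT_TABLE):
            assert subgroup_test(table, policy="auto").test_used == "pearson"

    def test_low_expected_count_switches_to_fisher(self):
        res = subgroup_test([[3, 4], [5, 2]], policy="auto")
        assert res.test_used == "fisher"
        expect = stats.fisher_exact([[3, 4], [5, 2]])[1]
        assert res.p_value == pytest.approx(expect)

    def test_zero_row_dropped_with_df_adjusted(self):
        res = subgroup_test(
            [[50, 60], [0, 0], [70, 40]], categories=("a", "b", "c"),
            policy="pearson",
        )
        assert res.categories == ("a", "c")
        assert res.df == 1

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValidationError):
            subgroup_test([[5, 0], [7, 0]])

    def test_single_category_rejected(self):
        with pytest.raises(ValidationError):
            subgroup_test([[5, 5]])

    @given(st.permutations(list(range(4))))
    def test_chi2_invariant_under_row_permutation(self, perm):
        base = subgroup_test(AGE_TABLE, policy="pearson")
        table = [AGE_TABLE[i] for i in perm]
        res = subgroup_test(table, policy="pearson")
        assert res.chi2 == pytest.approx(base.chi2)
        assert res.p_value == pytest.approx(base.p_value)

    def test_pearson_fisher_agree_on_large_balanced_table(self):
        table = [[1000, 950], [980, 1030]]
        p_pearson = subgroup_test(table, policy="pearson").p_value
        p_fisher = subgroup_test(table, policy="fisher").p_value
        assert abs(p_pearson - p_fisher) < 0.01


class TestAgeRebin:
    def test_fda_warning_boundary_24_inclusive(self):
        ages = pd.Series([24.0, 24.01, 17.9, 65.0, np.nan])
        out = age_rebin(ages, scheme="fda_warning")
        assert out.tolist() == ["<=24", "25-64", "<=24", ">=65", MISSING]

    def test_table_scheme_boundaries(self):
        ages = pd.Series([17.9, 18.0, 64.9, 65.0, 85.0, 85.1, 200.0])
        out = age_rebin(ages, scheme="table")
        assert out.tolist() == ["<18", "18-64", "18-64", "65-85", "65-85",
                                ">85", ">85"]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError):
            age_rebin(pd.Series([30.0]), scheme="nope")

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        ages = pd.Series(rng.uniform(0, 100, 500))
        out = age_rebin(ages, scheme="fda_warning")
        assert (out == "<=24").sum() == int((ages <= 24.0 + 1e-9).sum())
        assert (out == ">=65").sum() == int((ages >= 65).sum())

    def test_weight_bins(self):
        w = pd.Series([49.9, 50.0, 100.0, 100.1, np.nan])
        assert weight_rebin(w).tolist() == ["<50", "50-100", "50-100", ">100",
                                            MISSING]


class TestLabelSuicide:
    def test_any_matching_pt_labels_report(self):
        reac = pd.DataFrame({
            "primaryid": ["1", "1", "2"],
            "pt": ["Nausea", "Suicidal ideation", "Nausea"],
        })
        assert label_suicide_reports(reac, SUICIDE_PTS) == {"1"}

    def test_empty_pt_list_rejected(self):
        with pytest.raises(ValidationError):
            label_suicide_reports(pd.DataFrame({"primaryid": [], "pt": []}), [])

    def test_matches_generator_planted_count(self, cohort, truth):
        suicide_idx = {
            i for i, name in enumerate(truth.event_names) if name in SUICIDE_PTS
        }
        expected_cases = {
            cid for cid, events in truth.report_events.items()
            if suicide_idx & set(events)
        }
        labelled = label_suicide_reports(cohort.reactions, SUICIDE_PTS)
        labelled_cases = set(
            cohort.records.loc[
                cohort.records["primaryid"].isin(labelled), "caseid"
            ].astype(int)
        )
        assert labelled_cases == expected_cases


def synthetic_records_cohort(sex_counts: dict[str, int]) -> Cohort:
    """Minimal cohort whose records carry only the sex distribution."""
    rows = []
    pid = 0
    for sex, count in sex_counts.items():
        for _ in range(count):
            rows.append({"primaryid": str(pid), "caseid": str(pid), "sex": sex,
                         "age_years": np.nan, "weight_kg": np.nan,
                         "country": "", "reporter": "",
                         "fda_date": pd.Timestamp("2020-01-01"),
                         "event_date": pd.NaT})
            pid += 1
    columns = ["primaryid", "caseid", "sex", "age_years", "weight_kg",
               "country", "reporter", "fda_date", "event_date"]
    records = pd.DataFrame(rows, columns=columns)
    records["fda_date"] = pd.to_datetime(records["fda_date"])
    empty_reac = pd.DataFrame(columns=["primaryid", "caseid", "pt", "pt_norm"])
    return Cohort(
        records=records, reactions=empty_reac,
        drugs=pd.DataFrame(), outcomes=pd.DataFrame(columns=["primaryid", "outc_cod"]),
        therapy_starts=pd.Series(dtype="datetime64[ns]"),
        target_ids=set(records["primaryid"]), report=IngestReport(),
    )


class TestCharacterize:
    def test_printed_sex_proportions_full_cohort(self):
        cohort = synthetic_records_cohort(
            {"Female": 8332, "Male": 3639, MISSING: 1727}
        )
        out = characterize(cohort)
        sex = out[out["factor"] == "sex"].set_index("category")
        assert sex.loc["Female", "proportion_pct"] == 60.83
        assert sex.loc["Male", "proportion_pct"] == 26.57
        assert sex.loc[MISSING, "proportion_pct"] == 12.61

    def test_printed_sex_proportions_suicide_cohort(self):
        cohort = synthetic_records_cohort(
            {"Female": 708, "Male": 459, MISSING: 106}
        )
        out = characterize(cohort)
        sex = out[out["factor"] == "sex"].set_index("category")
        assert sex.loc["Female", "proportion_pct"] == 55.62
        assert sex.loc["Male", "proportion_pct"] == 36.06

    def test_counts_sum_to_total_including_missing(self, cohort):
        out = characterize(cohort, ids=cohort.target_ids)
        for factor in ("sex", "age", "weight"):
            total = out.loc[out["factor"] == factor, "count"].sum()
            assert total == len(cohort.target_ids)

    def test_empty_cohort(self):
        cohort = synthetic_records_cohort({})
        out = characterize(cohort)
        assert (out["count"] == 0).all()

    def test_proportion_rounding(self):
        assert proportion_pct(8332, 13698) == 60.83
        assert proportion_pct(708, 1273) == 55.62


class TestSuicideSubgroupTables:
    def test_missing_excluded_from_tests(self, cohort):
        suicide_ids = label_suicide_reports(cohort.reactions, SUICIDE_PTS)
        suicide_ids &= cohort.target_ids
        tables = suicide_subgroup_tables(cohort, suicide_ids)
        by_factor = {t.factor: t for t in tables}
        assert MISSING not in by_factor["age"].categories
        # column sums equal non-missing target reports
        rec = cohort.records[cohort.records["primaryid"].isin(cohort.target_ids)]
        n_with_sex = int((rec["sex"] != MISSING).sum())
        assert by_factor["sex"].counts.sum() == n_with_sex
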