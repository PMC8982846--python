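"""Index-event identification, enrollment eligibility, and covariate coding."""

import numpy as np
import pandas as pd
import pytest

import opioidcohort as oc
from opioidcohort.cohort import (
    categorize_age,
    categorize_days_supply,
    categorize_mme,
    year_continuity,
)

from conftest import fills_frame, index_frame, make_fill


def spans_frame(rows):
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "start_date": pd.Timestamp(s),
                "end_date": pd.Timestamp(e),
                "plan": plan,
            }
            for pid, s, e, plan in rows
        ]
    )


EMPTY_CLAIMS = pd.DataFrame(columns=["patient_id", "service_date", "setting", "diagnosis_codes"])
EMPTY_DEATHS = pd.DataFrame(columns=["patient_id", "death_date"])


class TestFindIndexEvents:
    def test_first_ever_fill_qualifies(self, code_set):
        fills = fills_frame([make_fill(drug_base="oxycodone", fill_date="2016-05-01")])
        idx = oc.find_index_events(fills, EMPTY_CLAIMS, code_set)
        assert len(idx) == 1
        assert idx.iloc[0]["drug_group"] == "oxycodone_SA"
        assert idx.iloc[0]["index_year"] == 2016

    def test_prior_opioid_fill_within_lookback_disqualifies(self, code_set):
        fills = fills_frame(
            [
                make_fill(drug_base="codeine", fill_date="2016-01-21"),
                make_fill(drug_base="oxycodone", fill_date="2016-04-30"),  # 100 days later
            ]
        )
        idx = oc.find_index_events(fills, EMPTY_CLAIMS, code_set)
        assert len(idx) == 0

    def test_prior_opioid_claim_within_lookback_disqualifies(self, code_set):
        fills = fills_frame([make_fill(drug_base="oxycodone", fill_date="2016-07-19")])
        claims = pd.DataFrame(
            [
                {
                    "patient_id": "P1",
                    "service_date": pd.Timestamp("2016-01-01"),  # 200 days before
                    "setting": "ED",
                    "diagnosis_codes": ["T40.2X1A"],
                }
            ]
        )
        assert len(oc.find_index_events(fills, claims, code_set)) == 0

    def test_fill_older_than_lookback_is_ignored(self, code_set):
        fills = fills_frame(
            [
                make_fill(drug_base="codeine", fill_date="2015-01-01"),
                make_fill(drug_base="oxycodone", fill_date="2016-06-01"),
            ]
        )
        idx = oc.find_index_events(fills, EMPTY_CLAIMS, code_set)
        assert len(idx) == 1
        assert idx.iloc[0]["index_date"] == pd.Timestamp("2016-06-01")

    def test_long_acting_fills_never_index(self, code_set):
        fills = fills_frame([make_fill(drug_base="oxycodone", long_acting=True)])
        assert len(oc.find_index_events(fills, EMPTY_CLAIMS, code_set)) == 0

    def test_one_event_per_patient_earliest_qualifying(self, code_set):
        fills = fills_frame(
            [
                make_fill(fill_date="2015-02-01", drug_base="hydrocodone"),
                make_fill(fill_date="2015-03-01", drug_base="oxycodone"),
            ]
        )
        idx = oc.find_index_events(fills, EMPTY_CLAIMS, code_set)
        assert len(idx) == 1
        assert idx.iloc[0]["drug_base"] == "hydrocodone"

    def test_naive_property_brute_force(self, code_set, small_population):
        """Every emitted index event survives an exhaustive lookback scan."""
        _, tables, _ = small_population
        kept, _ = oc.clean_fills(tables.fills)
        idx = oc.find_index_events(kept, tables.claims, code_set)
        assert idx["patient_id"].is_unique
        by_pat_fills = dict(tuple(kept.groupby("patient_id")))
        oc_claims = tables.claims[tables.claims["diagnosis_codes"].map(code_set.matches_nonfatal)]
        by_pat_claims = dict(tuple(oc_claims.groupby("patient_id")))
        sample = idx.sample(n=min(len(idx), 300), random_state=0)
        for row in sample.itertuples():
            lo = row.index_date - pd.Timedelta(days=365)
            f = by_pat_fills[row.patient_id]
            assert not ((f["fill_date"] >= lo) & (f["fill_date"] < row.index_date)).any()
            c = by_pat_claims.get(row.patient_id)
            if c is not None:
                assert not ((c["service_date"] >= lo) & (c["service_date"] < row.index_date)).any()


class TestEnrollmentFilter:
    def test_full_year_span_kept(self):
        idx = index_frame(index_date="2016-04-01")
        spans = spans_frame([("P1", "2016-01-01", "2017-01-01", "commercial")])
        kept, excluded = oc.apply_enrollment_filter(idx, spans, EMPTY_DEATHS)
        assert len(kept) == 1 and len(excluded) == 0

    @pytest.mark.parametrize("gap_days,expect_kept", [(89, True), (90, False)])
    def test_gap_boundary(self, gap_days, expect_kept):
        idx = index_frame(index_date="2016-02-01")
        resume = pd.Timestamp("2016-04-01") + pd.Timedelta(days=gap_days)
        spans = spans_frame(
            [
                ("P1", "2016-01-01", "2016-04-01", "commercial"),
                ("P1", str(resume.date()), "2017-01-01", "commercial"),
            ]
        )
        kept, excluded = oc.apply_enrollment_filter(idx, spans, EMPTY_DEATHS)
        assert (len(kept) == 1) == expect_kept
        if not expect_kept:
            assert excluded.iloc[0]["reason"] == "enrollment_gap"

    def test_deceased_exception_keeps_patient(self):
        idx = index_frame(index_date="2016-02-01")
        spans = spans_frame([("P1", "2016-01-01", "2016-03-01", "commercial")])
        deaths = pd.DataFrame([{"patient_id": "P1", "death_date": pd.Timestamp("2016-03-15")}])
        kept, _ = oc.apply_enrollment_filter(idx, spans, deaths)
        assert len(kept) == 1

    def test_no_spans_excluded_with_reason(self):
        idx = index_frame(index_date="2016-02-01")
        kept, excluded = oc.apply_enrollment_filter(idx, spans_frame([]).reindex(columns=["patient_id", "start_date", "end_date", "plan"]), EMPTY_DEATHS)
        assert len(kept) == 0
        assert excluded.iloc[0]["reason"] == "no_enrollment"

    def test_year_continuity_ignores_out_of_year_gaps(self):
        spans = spans_frame([("P1", "2015-01-01", "2016-06-01", "commercial"), ("P1", "2016-10-01", "2017-06-01", "commercial")])
        assert not year_continuity(spans, 2016)  # 122-day in-year gap
        assert year_continuity(spans, 2015)


class TestIndexMME:
    def test_forty_five_mg_oxycodone_tablets(self, mme_table):
        fill = make_fill(drug_base="oxycodone", strength_per_unit=5, quantity=40)
        assert oc.compute_index_mme(fill, mme_table) == 300.0

    def test_unit_factor_hydrocodone(self, mme_table):
        fill = make_fill(drug_base="hydrocodone", strength_per_unit=5, quantity=10)
        assert oc.compute_index_mme(fill, mme_table) == 50.0

    def test_codeine_factor(self, mme_table):
        fill = make_fill(drug_base="codeine", strength_per_unit=30, quantity=20)
        assert oc.compute_index_mme(fill, mme_table) == pytest.approx(90.0)

    def test_unknown_drug_raises_naming_it(self, mme_table):
        fill = make_fill(drug_base="opium")
        with pytest.raises(KeyError, match="opium"):
            oc.compute_index_mme(fill, mme_table)


class TestCategorize:
    def test_mme_bin_boundaries(self):
        assert list(categorize_mme([75, 75.5, 100, 101, 200, 300, 300.5])) == [
            "<=75", "76-100", "76-100", "101-200", "101-200", "201-300", ">300",
        ]

    def test_days_supply_bins(self):
        assert list(categorize_days_supply([3, 4, 6, 7])) == ["<=3", "4-6", "4-6", "7+"]

    def test_age_bins(self):
        assert list(categorize_age([18, 24, 25, 74, 75, 90])) == [
            "18-24", "18-24", "25-34", "65-74", "75+", "75+",
        ]

    def test_category_partition_property(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 600, 500)
        cats = categorize_mme(values)
        assert not cats.isin(["nan"]).any()  # every value lands in exactly one bin

    def test_insurance_requires_183_days(self, mme_table):
        idx = index_frame(index_date="2016-03-01")
        demo = pd.DataFrame(
            [{"patient_id": "P1", "age_years": 40, "gender": "F", "race_ethnicity": "White", "urbanization": "noncore"}]
        )
        spans = spans_frame(
            [
                ("P1", "2016-01-01", "2016-07-19", "medicaid"),  # 200 days
                ("P1", "2016-07-19", "2016-12-31", "commercial"),  # 165 days
            ]
        )
        cohort = oc.categorize(idx, demo, spans, mme_table)
        assert cohort.iloc[0]["insurance"] == "medicaid"
        spans_short = spans_frame([("P1", "2016-01-01", "2016-05-01", "medicaid")])
        cohort2 = oc.categorize(idx, demo, spans_short, mme_table)
        assert cohort2.iloc[0]["insurance"] == "unknown"

    def test_cohort_row_consistency(self, mme_table, small_population):
        """Every categorical drawn from its level set; MME category matches value."""
        _, tables, _ = small_population
        kept, _ = oc.clean_fills(tables.fills)
        idx = oc.find_index_events(kept, tables.claims, oc.load_code_set())
        k2, _ = oc.apply_enrollment_filter(idx, tables.spans, tables.deaths)
        cohort = oc.categorize(k2, tables.demographics, tables.spans, mme_table)
        assert cohort["patient_id"].is_unique
        recomputed = categorize_mme(cohort["index_mme"].to_numpy())
        assert (recomputed.to_numpy() == cohort["mme_category"].to_numpy()).all()
        from opioidcohort.cohort import AGE_LABELS, MME_LABELS, DAYS_SUPPLY_LABELS
        assert set(cohort["age_category"]) <= set(AGE_LABELS)
        assert set(cohort["mme_category"]) <= set(MME_LABELS)
        assert set(cohort["days_supply_category"]) <= set(DAYS_SUPPLY_LABELS)


class TestCombinationSubgroup:
    @pytest.mark.parametrize(
        "drug,combo,strength,expected",
        [
            ("oxycodone", "none", 5.0, "oxy_mono_5mg"),
            ("oxycodone", "acetaminophen", 5.0, "oxy_apap_5mg"),
            ("hydrocodone", "acetaminophen", 5.0, "hydro_apap_5mg"),
            ("oxycodone", "acetaminophen", 10.0, "other"),
            ("hydrocodone", "ibuprofen", 5.0, "other"),
        ],
    )
    def test_labels(self, drug, combo, strength, expected):
        idx = index_frame(drug_base=drug, combination_ingredient=combo, strength_per_unit=strength)
        assert oc.recode_combination_subgroup(idx).iloc[0] == expected
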