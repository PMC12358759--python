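"""Demographics/lab comparison, lab-group coding, report redaction, formatting."""

from __future__ import annotations

from dataclasses import replace
from datetime import date
from decimal import Decimal

import pytest

from linkbox.compare_reports import (
    ConfigurationError,
    RedactionError,
    build_report,
    compare_demographics,
    compare_labs,
    format_percent,
    recipient_kinds,
)
from linkbox.dedup import cluster_by_person
from linkbox.filter_stage import reconcile
from linkbox.match_engine import MatchResult
from linkbox.records import DemographicProfile

from conftest import make_central, make_lab, make_site, make_surv


class TestFormatPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (9060, 9744, "93.0"),
            (9257, 9378, "98.7"),
            (105, 121, "86.8"),
            (4315, 8028, "53.7"),
            (1, 8, "12.5"),
            (1, 800, "0.1"),
            (125, 1000, "12.5"),
            (1, 1, "100.0"),
        ],
    )
    def test_round_half_up_to_one_decimal(self, num, den, expected):
        assert format_percent(num, den) == expected

    def test_half_up_not_bankers(self):
        # 0.25% rounds up to 0.3, not to even
        assert format_percent(25, 10000) == "0.3"


class TestCompareDemographics:
    def test_identical_profiles_produce_no_rows(self):
        profile = make_central().demographics
        assert compare_demographics(profile, profile) == []

    def test_conflicting_diagnosis_dates_carry_both_values(self):
        cohort = make_central().demographics  # hiv_diagnosis_date 2010-03-01
        surv = replace(cohort, hiv_diagnosis_date=date(2009, 11, 15))
        rows = compare_demographics(cohort, surv, ["hiv_diagnosis_date"])
        assert len(rows) == 1
        row = rows[0]
        assert row.kind == "conflict"
        assert row.cohort_value == date(2010, 3, 1)
        assert row.surveillance_value == date(2009, 11, 15)

    def test_missing_race_in_cohort(self):
        surv = make_central().demographics
        cohort = replace(surv, race=None)
        rows = compare_demographics(cohort, surv, ["race"])
        assert [r.kind for r in rows] == ["missing_in_cohort"]

    def test_canonicalization_ignores_case_and_whitespace(self):
        a = make_central().demographics
        b = replace(a, race=" BLACK ")
        assert compare_demographics(a, b) == []

    def test_unknown_field_is_a_configuration_error(self):
        profile = make_central().demographics
        with pytest.raises(ConfigurationError):
            compare_demographics(profile, profile, ["shoe_size"])


class TestCompareLabs:
    consent = date(2015, 6, 1)

    def test_identical_lab_is_duplicate_and_in_no_new_list(self):
        lab = make_lab()
        cmp = compare_labs([lab], [replace(lab, facility="LABCORP DC")], self.consent)
        assert [code for _, _, code in cmp.coded_pairs] == ["DUPLICATE"]
        assert cmp.new_to_cohort == [] and cmp.new_to_surveillance == []

    def test_pre_consent_surveillance_lab_is_excluded_entirely(self):
        early = make_lab(sample_date=date(2015, 6, 1))  # on consent date: excluded
        cmp = compare_labs([], [early], self.consent)
        assert cmp.new_to_cohort == []
        assert cmp.coded_pairs == []

    def test_surveillance_only_lab_after_consent_is_new_to_cohort(self):
        lab = make_lab(sample_date=date(2016, 2, 2))
        cmp = compare_labs([], [lab], self.consent)
        assert cmp.new_to_cohort == [lab]

    def test_result_difference_is_coded(self):
        a = make_lab(result=Decimal(200))
        b = make_lab(result=Decimal(210))
        cmp = compare_labs([a], [b], self.consent)
        assert [code for _, _, code in cmp.coded_pairs] == ["RESULT_DIFF"]

    def test_interpretation_difference_is_coded(self):
        a = make_lab(lab_type="viral_load", result=Decimal(20), interpretation="EQ")
        b = make_lab(lab_type="viral_load", result=Decimal(20),
                     interpretation="UNDETECTABLE")
        cmp = compare_labs([a], [b], self.consent)
        assert [code for _, _, code in cmp.coded_pairs] == ["RESULT_INTERP_DIFF"]

    def test_trailing_zeros_do_not_break_equality(self):
        a = make_lab(result=Decimal("200.0"))
        b = make_lab(result=Decimal("200"))
        cmp = compare_labs([a], [b], self.consent)
        assert [code for _, _, code in cmp.coded_pairs] == ["DUPLICATE"]

    def test_greedy_pairing_in_result_sorted_order(self):
        # two same-day same-type labs per side pair low-low / high-high
        c = [make_lab(result=Decimal(300)), make_lab(result=Decimal(100))]
        s = [make_lab(result=Decimal(100)), make_lab(result=Decimal(350))]
        cmp = compare_labs(c, s, self.consent)
        results = [(p[0].result, p[1].result, p[2]) for p in cmp.coded_pairs]
        assert results == [
            (Decimal(100), Decimal(100), "DUPLICATE"),
            (Decimal(300), Decimal(350), "RESULT_DIFF"),
        ]

    def test_lab_conservation(self):
        cohort = [make_lab(sample_date=date(2016, 1, i)) for i in range(1, 6)]
        surv = [make_lab(sample_date=date(2016, 1, i)) for i in range(3, 10)]
        pre = [make_lab(sample_date=date(2014, 1, 1))]
        cmp = compare_labs(cohort, surv + pre, self.consent)
        assert len(cohort) == len(cmp.coded_pairs) + len(cmp.new_to_surveillance)
        assert len(surv) == len(cmp.coded_pairs) + len(cmp.new_to_cohort)


def _pipeline_inputs():
    """A tiny matched universe: two shared matches, one unmatched eligible."""
    sites = [
        make_site(cohort_id="C1"),
        make_site(cohort_id="C2", first_name="Jane", last_name="Doe",
                  dob=date(1975, 11, 20), ssn="912345678", birth_sex="F",
                  site_id="S02"),
        make_site(cohort_id="C3", first_name="Sam", last_name="Poe",
                  dob=date(1969, 4, 1), ssn="934567890"),
    ]
    centrals = [
        make_central(cohort_id="C1", labs=(make_lab(),),
                     treatments=(("Biktarvy", date(2016, 1, 1), None),)),
        make_central(cohort_id="C2"),
        make_central(cohort_id="C3"),
    ]
    survs = [
        make_surv(person_id="P1", prior_cohort_id="C1",
                  labs=(make_lab(facility="LABCORP DC"),
                        make_lab(sample_date=date(2017, 3, 3), facility="LABCORP DC")),
                  opportunistic_infections=(("Kaposi sarcoma", date(2018, 1, 1)),)),
        make_surv(person_id="P2", first_name="Jane", last_name="Doe",
                  dob=date(1975, 11, 20), ssn="912345678", birth_sex="F"),
    ]
    outcome = reconcile(centrals, sites)
    results = [
        MatchResult("C1", "P1", 100, "FULL_NAME/x", "person_view", True),
        MatchResult("C2", "P2", 98, "FULL_NAME/x", "person_view", True),
    ]
    clusters = cluster_by_person(results)
    return {
        "results": results,
        "eligible": outcome.eligible,
        "eligible_by_id": {e.cohort_id: e for e in outcome.eligible},
        "surveillance_by_id": {s.person_id: s for s in survs},
        "clusters": clusters,
        "filter_outcome": outcome,
    }


class TestBuildReport:
    def test_cohort_match_report_has_only_id_and_score(self):
        frame = build_report("match", "cohort", _pipeline_inputs())
        assert list(frame.columns) == ["cohort_id", "score"]
        assert len(frame) == 2

    def test_health_dept_match_report_carries_identifiers(self):
        frame = build_report("match", "health_dept", _pipeline_inputs())
        assert {"person_id", "first_name", "dob", "ssn"} <= set(frame.columns)
        assert frame.loc[0, "ssn"] == "987654321"

    def test_unmatched_report(self):
        frame = build_report("unmatched", "cohort", _pipeline_inputs())
        assert frame["cohort_id"].tolist() == ["C3"]

    def test_unmatched_report_empty_when_everyone_matched(self):
        inputs = _pipeline_inputs()
        inputs["eligible"] = [e for e in inputs["eligible"] if e.cohort_id != "C3"]
        frame = build_report("unmatched", "cohort", inputs)
        assert frame.empty

    def test_cohort_unmatched_merges_filtered_and_unmatched_with_reasons(self):
        inputs = _pipeline_inputs()
        inputs["filter_outcome"].central_only_ids.append("C0")
        frame = build_report("cohort_unmatched", "cohort", inputs)
        reasons = dict(zip(frame["cohort_id"], frame["reason"]))
        assert reasons == {
            "C0": "not_in_site_files",
            "C3": "no_surveillance_match",
        }

    def test_labs_report_codes_and_new_rows(self):
        frame = build_report("labs", "cohort", _pipeline_inputs())
        c1 = frame[frame["cohort_id"] == "C1"]
        assert set(c1["lab_group"]) == {"DUPLICATE", "NEW"}
        new_row = c1[c1["lab_group"] == "NEW"].iloc[0]
        assert new_row["new_to"] == "cohort"

    def test_lab_site_report_lists_facilities(self):
        frame = build_report("lab_site", "cohort", _pipeline_inputs())
        assert frame.iloc[0]["facility"] == "LABCORP DC"
        assert frame.iloc[0]["n_labs"] == 2

    def test_oi_report(self):
        frame = build_report("oi", "cohort", _pipeline_inputs())
        assert frame["condition"].tolist() == ["Kaposi sarcoma"]

    def test_treatment_report_for_cohort_is_a_redaction_error(self):
        with pytest.raises(RedactionError):
            build_report("treatment", "cohort", _pipeline_inputs())

    def test_treatment_report_for_health_dept(self):
        frame = build_report("treatment", "health_dept", _pipeline_inputs())
        assert frame["drug"].tolist() == ["Biktarvy"]

    def test_multi_site_report_redacts_person_id_for_cohort(self):
        inputs = _pipeline_inputs()
        inputs["results"].append(
            MatchResult("C3", "P1", 90, "FULL_NAME/x", "person_view", True)
        )
        inputs["clusters"] = cluster_by_person(inputs["results"])
        cohort_frame = build_report("multi_site", "cohort", inputs)
        hd_frame = build_report("multi_site", "health_dept", inputs)
        assert "person_id" not in cohort_frame.columns
        assert cohort_frame.iloc[0]["cohort_ids"] == "C1;C3"
        assert hd_frame.iloc[0]["person_id"] == "P1"

    def test_filter_report(self):
        inputs = _pipeline_inputs()
        inputs["filter_outcome"].central_only_ids.append("C0")
        frame = build_report("filter", "cohort", inputs)
        assert ("C0", "site_files") in list(
            zip(frame["cohort_id"], frame["missing_from"])
        )

    def test_unknown_kind_and_recipient_rejected(self):
        with pytest.raises(ConfigurationError):
            build_report("bogus", "cohort", {})
        with pytest.raises(ConfigurationError):
            build_report("match", "press", {})

    def test_every_cohort_kind_is_free_of_identifier_columns(self):
        inputs = _pipeline_inputs()
        banned = {"person_id", "first_name", "last_name", "dob", "ssn", "birth_sex"}
        for kind in recipient_kinds("cohort"):
            frame = build_report(kind, "cohort", inputs)
            assert not banned & set(frame.columns), kind

    def test_demographics_report_rows_only_on_discrepancy(self):
        inputs = _pipeline_inputs()
        surv = inputs["surveillance_by_id"]["P2"]
        inputs["surveillance_by_id"]["P2"] = replace(
            surv, demographics=replace(surv.demographics, race="White")
        )
        # P1's profile matches the central default exactly -> no P1 rows
        inputs["surveillance_by_id"]["P1"] = replace(
            inputs["surveillance_by_id"]["P1"],
            demographics=make_central().demographics,
        )
        frame = build_report("demographics", "cohort", inputs)
        assert set(frame["cohort_id"]) == {"C2"}
        row = frame[frame["field"] == "race"].iloc[0]
        assert row["kind"] == "conflict"
        assert row["surveillance_value"] == "White"
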