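"""Name normalization, the scoring cascade, blocking, and best-match selection."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkbox.match_engine import (
    MatchAlgorithm,
    MatchLevel,
    default_algorithm,
    generate_candidates,
    normalize_name,
    run_match,
    score_pair,
)

from conftest import make_site, make_surv


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("O'Brien-Smith ", "OBRIENSMITH"),
            ("smith", "SMITH"),
            ("SMITH", "SMITH"),
            ("  de la Cruz Jr.", "DELACRUZJR"),
            ("---", None),
            ("", None),
            (None, None),
        ],
    )
    def test_normalization_rules(self, raw, expected):
        assert normalize_name(raw) == expected

    @given(st.text(alphabet=st.characters(categories=("Lu", "Ll")), max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_idempotent_and_case_insensitive(self, raw):
        token = normalize_name(raw)
        assert normalize_name(raw.lower()) == token
        if token is not None:
            assert normalize_name(token) == token


class TestDefaultAlgorithm:
    def test_shipped_cascade_shape(self):
        alg = default_algorithm()
        assert len(alg.levels) == 28
        assert alg.threshold == 61
        scores = alg.defined_scores
        assert max(scores) == 100 and min(scores) == 20
        assert len(scores) == len(set(scores))

    def test_alias_scores_one_below_person_view(self):
        for level in default_algorithm().levels:
            if level.score_alias is not None:
                assert level.score_alias == level.score_person_view - 1

    def test_every_level_requires_a_blocking_variable(self):
        # justifies blocking on {cohort_id, dob, ssn_last4}
        blocking = {"COHORT_ID", "DOB", "SSN_FULL", "SSN_PARTIAL"}
        for level in default_algorithm().levels:
            assert level.required_vars & blocking

    def test_json_round_trip(self):
        alg = default_algorithm()
        assert MatchAlgorithm.from_json(alg.to_json()) == alg

    def test_duplicate_scores_rejected(self):
        level = MatchLevel("NONE", frozenset({"DOB"}), 50)
        with pytest.raises(ValueError):
            MatchAlgorithm(levels=(level, level))


def _score(site_kw, surv_kw):
    scored = score_pair(make_site(**site_kw), make_surv(**surv_kw))
    return scored


class TestScorePair:
    def test_full_agreement_scores_100(self):
        score, _level, source = _score({}, {"prior_cohort_id": "C000001"})
        assert score == 100
        assert source == "person_view"

    def test_alias_full_agreement_scores_99(self):
        score, _level, source = _score(
            {},
            {
                "first_name": "Jonathan",
                "last_name": "Smythe",
                "aliases": (("John", "Smith"),),
                "prior_cohort_id": "C000001",
            },
        )
        assert score == 99
        assert source == "alias"

    def test_cohort_id_only_scores_20(self):
        score, _level, source = _score(
            {"ssn": None, "birth_sex": "unknown"},
            {
                "first_name": "Ann",
                "last_name": "Lee",
                "dob": date(1990, 9, 9),
                "ssn": None,
                "birth_sex": "F",
                "prior_cohort_id": "C000001",
            },
        )
        assert score == 20
        assert source == "none"

    def test_dob_ssn_without_name_scores_61_and_shared(self):
        score, _level, _source = _score(
            {"birth_sex": "unknown"},
            {"first_name": "Ann", "last_name": "Lee", "birth_sex": "F"},
        )
        assert score == 61
        assert score >= default_algorithm().threshold

    def test_prior_cohort_id_lifts_61_to_62(self):
        score, _, _ = _score(
            {"birth_sex": "unknown"},
            {
                "first_name": "Ann",
                "last_name": "Lee",
                "birth_sex": "F",
                "prior_cohort_id": "C000001",
            },
        )
        assert score == 62

    def test_partial_ssn_satisfies_partial_level_only(self):
        # a 4-digit stored SSN can satisfy SSN_PARTIAL but never SSN_FULL
        score, _, _ = _score({"ssn": "4321"}, {"prior_cohort_id": "C000001"})
        assert score == 95  # not 100
        score, _, _ = _score({"ssn": "4321"}, {})
        assert score == 93  # not 98

    def test_first6_level(self):
        base_surv = {"first_name": "Jonathon", "ssn": None, "birth_sex": "unknown"}
        score, _, _ = _score({"first_name": "Jonathan", "ssn": None, "birth_sex": "unknown"},
                             base_surv)
        assert score == 63
        score, _, _ = _score({"first_name": "Jonathan", "ssn": None, "birth_sex": "unknown"},
                             {**base_surv, "prior_cohort_id": "C000001"})
        assert score == 64

    def test_last_name_only_levels(self):
        # last name + DOB + SSN (no first-name agreement) -> 65; with cohort ID -> 66
        site = {"first_name": "Jonathan", "birth_sex": "unknown"}
        surv = {"first_name": "Marcus", "birth_sex": "unknown"}
        assert _score(site, surv)[0] == 65
        assert _score(site, {**surv, "prior_cohort_id": "C000001"})[0] == 66
        # last name + DOB only -> 59 (below threshold)
        score, _, _ = _score(
            {**site, "ssn": None}, {**surv, "ssn": None}
        )
        assert score == 59
        assert score < default_algorithm().threshold

    def test_alias_never_satisfies_last_only_levels(self):
        # person-view last name differs; alias agrees on last name only
        site = {"first_name": "Jonathan", "birth_sex": "unknown"}
        surv = {
            "first_name": "Marcus",
            "last_name": "Smythe",
            "aliases": (("Marcus", "Smith"),),
            "birth_sex": "unknown",
        }
        assert _score(site, surv)[0] == 61  # DOB+SSN floor, not 65

    def test_missing_fields_are_unsatisfied_not_errors(self):
        score = _score(
            {"ssn": None, "dob": None, "birth_sex": "unknown"},
            {"first_name": "Ann", "last_name": "Lee", "ssn": None},
        )
        assert score is None

    def test_disjoint_records_do_not_match(self):
        assert _score(
            {},
            {
                "first_name": "Ann",
                "last_name": "Lee",
                "dob": date(1955, 5, 5),
                "ssn": "911111111",
                "birth_sex": "F",
            },
        ) is None

    def test_unknown_birth_sex_never_agrees(self):
        # both unknown: BIRTH_SEX unsatisfied -> 90, not 100
        score, _, _ = _score(
            {"birth_sex": "unknown"},
            {"birth_sex": "unknown", "prior_cohort_id": "C000001"},
        )
        assert score == 90

    def test_alias_penalty_is_exactly_one(self):
        """Replacing person-view name agreement by alias-only agreement at the
        same level lowers the score by exactly 1."""
        variants = [
            ({}, {"prior_cohort_id": "C000001"}),  # level 100
            ({}, {}),  # level 98
            ({"ssn": "4321"}, {}),  # level 93
            ({"ssn": None}, {"ssn": None}),  # level 80
        ]
        for site_kw, surv_kw in variants:
            pv_score = _score(site_kw, surv_kw)[0]
            alias_kw = {
                **surv_kw,
                "first_name": "Zed",
                "last_name": "Zulu",
                "aliases": (("John", "Smith"),),
            }
            alias_score, _, alias_source = _score(site_kw, alias_kw)
            assert alias_source == "alias"
            assert alias_score == pv_score - 1


agreement_flags = st.fixed_dictionaries(
    {
        "name": st.sampled_from(["pv", "alias", "none"]),
        "dob": st.booleans(),
        "ssn": st.sampled_from(["full", "partial", "none"]),
        "sex": st.booleans(),
        "cohort": st.booleans(),
    }
)


def _pair_from_flags(flags):
    site_kw = {}
    surv_kw = {}
    if flags["name"] == "alias":
        surv_kw.update(
            first_name="Zed", last_name="Zulu", aliases=(("John", "Smith"),)
        )
    elif flags["name"] == "none":
        surv_kw.update(first_name="Zed", last_name="Zulu")
    if not flags["dob"]:
        surv_kw["dob"] = date(1999, 12, 31)
    if flags["ssn"] == "partial":
        site_kw["ssn"] = "4321"
    elif flags["ssn"] == "none":
        site_kw["ssn"] = None
    if not flags["sex"]:
        site_kw["birth_sex"] = "unknown"
    if flags["cohort"]:
        surv_kw["prior_cohort_id"] = "C000001"
    return site_kw, surv_kw


class TestScoreMonotonicity:
    @given(agreement_flags)
    @settings(max_examples=200, derandomize=True)
    def test_adding_an_agreeing_field_never_lowers_the_score(self, flags):
        site_kw, surv_kw = _pair_from_flags(flags)
        base = _score(site_kw, surv_kw)
        base_score = base[0] if base else 0
        for upgrade in ("dob", "sex", "cohort"):
            if flags[upgrade]:
                continue
            up_site, up_surv = _pair_from_flags({**flags, upgrade: True})
            upgraded = _score(up_site, up_surv)
            up_score = upgraded[0] if upgraded else 0
            assert up_score >= base_score
        if flags["ssn"] != "full":
            up_site, up_surv = _pair_from_flags({**flags, "ssn": "full"})
            upgraded = _score(up_site, up_surv)
            up_score = upgraded[0] if upgraded else 0
            assert up_score >= base_score


class TestCandidates:
    def test_shared_last_name_only_is_not_a_candidate(self):
        site = make_site(ssn=None, dob=date(1970, 1, 1))
        surv = make_surv(
            first_name="Ann", ssn=None, dob=date(1980, 5, 5), prior_cohort_id=None
        )
        assert generate_candidates([site], [surv]) == []
        assert score_pair(site, surv) is None  # provably unscorable

    def test_shared_dob_only_is_a_candidate(self):
        site = make_site(ssn=None)
        surv = make_surv(
            first_name="Ann", last_name="Lee", ssn=None, prior_cohort_id=None
        )
        assert generate_candidates([site], [surv]) == [(0, 0)]

    def test_disjoint_keys_yield_no_candidates(self):
        site = make_site()
        surv = make_surv(
            dob=date(1999, 1, 1), ssn="900000000", prior_cohort_id=None
        )
        assert generate_candidates([site], [surv]) == []


class TestRunMatch:
    def test_highest_scoring_person_wins(self):
        site = make_site()
        strong = make_surv(person_id="P1", prior_cohort_id="C000001")  # 100
        weak = make_surv(
            person_id="P2", first_name="Ann", last_name="Lee", birth_sex="F"
        )  # 61
        results = run_match([site], [strong, weak])
        assert len(results) == 1
        assert results[0].person_id == "P1"
        assert results[0].score == 100
        assert not results[0].tie_flag

    def test_two_cohort_ids_may_map_to_one_person(self):
        sites = [make_site(cohort_id="C1"), make_site(cohort_id="C2", site_id="S02")]
        surv = make_surv(person_id="P1")
        results = run_match(sites, [surv])
        assert [r.cohort_id for r in results] == ["C1", "C2"]
        assert {r.person_id for r in results} == {"P1"}

    def test_equal_score_tie_prefers_smallest_person_id(self):
        site = make_site()
        p2 = make_surv(person_id="P2")
        p1 = make_surv(person_id="P1")
        results = run_match([site], [p2, p1])
        assert results[0].person_id == "P1"
        assert results[0].tie_flag

    def test_shared_flag_tracks_threshold(self):
        site = make_site(birth_sex="unknown")
        surv61 = make_surv(first_name="Ann", last_name="Lee", birth_sex="F")
        surv59 = make_surv(
            person_id="P9", first_name="Ann", ssn=None, birth_sex="F"
        )
        results = run_match([site], [surv61])
        assert results[0].shared
        results = run_match([site], [surv59])
        assert results[0].score == 59
        assert not results[0].shared

    def test_deterministic_output(self):
        sites = [make_site(cohort_id=f"C{i}") for i in range(5)]
        survs = [make_surv(person_id=f"P{i}") for i in range(5)]
        assert run_match(sites, survs) == run_match(sites, survs)
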