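"""Shared fixtures and record factories for the test suite."""

from __future__ import annotations

from datetime import date
from decimal import Decimal

import pytest

from linkbox.records import (
    CentralRecord,
    DemographicProfile,
    LabRecord,
    SiteRecord,
    SurveillanceRecord,
)


def make_site(**kw) -> SiteRecord:
    base = dict(
        cohort_id="C000001",
        site_id="S01",
        first_name="John",
        last_name="Smith",
        dob=date(1980, 2, 3),
        ssn="987654321",
        birth_sex="M",
    )
    base.update(kw)
    return SiteRecord(**base)


def make_surv(**kw) -> SurveillanceRecord:
    base = dict(
        person_id="P000001",
        first_name="John",
        last_name="Smith",
        aliases=(),
        dob=date(1980, 2, 3),
        ssn="987654321",
        birth_sex="M",
        prior_cohort_id=None,
    )
    base.update(kw)
    return SurveillanceRecord(**base)


def make_central(**kw) -> CentralRecord:
    base = dict(
        cohort_id="C000001",
        consent_date=date(2015, 6, 1),
        demographics=DemographicProfile(
            vital_status="alive",
            gender="M",
            sex_at_birth="M",
            race="Black",
            hiv_transmission_risk="MSM",
            state_of_residence="DC",
            hiv_diagnosis_date=date(2010, 3, 1),
        ),
    )
    base.update(kw)
    return CentralRecord(**base)


def make_lab(**kw) -> LabRecord:
    base = dict(
        sample_date=date(2016, 1, 15),
        lab_type="CD4_count",
        result=Decimal(500),
        interpretation="EQ",
    )
    base.update(kw)
    return LabRecord(**base)


@pytest.fixture
def site_csv(tmp_path):
    """A well-formed 3-row site file."""
    path = tmp_path / "site.csv"
    path.write_text(
        "cohort_id,site_id,first_name,last_name,dob,ssn,birth_sex\n"
        "C000001,S01,John,Smith,1980-02-03,987-65-4321,M\n"
        "C000002,S01,Jane,Doe,1975-11-20,4321,F\n"
        "C000003,S01,Alex,O'Brien-Smith,1990-07-07,,\n",
        encoding="utf-8",
    )
    return path
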