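"""Cohort-ID reconciliation between the central file and the site files.

Before any matching against the registry, the Cohort IDs in the central
(deidentified) file are checked against those submitted by the clinic
sites.  Only IDs present in both feeds proceed to matching; the rest are
written to two filter reports (central-only and site-only) delivered to
both recipients.  A Cohort ID enrolled at several sites enters eligibility
once — the first-seen site row supplies the matching identifiers — but all
site rows are retained for per-site reporting, and any disagreement between
sites on the identifiers is recorded in a conflict report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

from .records import CentralRecord, SiteRecord

__all__ = ["EligibleRecord", "FilterOutcome", "IdentifierConflict", "reconcile"]


@dataclass(frozen=True)
class EligibleRecord:
    """Site identifiers merged with the central payload for one Cohort ID."""

    cohort_id: str
    site_id: str  # first-seen site (supplies the matching identifiers)
    site_ids: tuple[str, ...]  # every site where this cohort_id appears
    first_name: Optional[str]
    last_name: Optional[str]
    dob: Optional[date]
    ssn: Optional[str]
    birth_sex: str
    central: CentralRecord


@dataclass(frozen=True)
class IdentifierConflict:
    cohort_id: str
    field: str
    kept: object
    conflicting: object
    site_id: str  # site whose value was discarded


_IDENTIFIER_FIELDS = ("first_name", "last_name", "dob", "ssn", "birth_sex")


@dataclass
class FilterOutcome:
    eligible: list[EligibleRecord]
    central_only_ids: list[str]
    site_only_ids: list[str]
    conflicts: list[IdentifierConflict] = field(default_factory=list)


def reconcile(
    central_records: Sequence[CentralRecord],
    site_records: Sequence[SiteRecord],
) -> FilterOutcome:
    """Intersect central and site Cohort IDs into the eligible match set.

    Returns the eligible merged records (sorted by cohort_id) together with
    the two exclusion lists.  Every input cohort_id lands in exactly one of
    {eligible, central_only, site_only}.  Cross-site identifier conflicts
    are resolved first-seen-wins and reported.
    """
    central_by_id = {}
    for rec in central_records:
        central_by_id[rec.cohort_id] = rec

    site_rows: dict[str, list[SiteRecord]] = {}
    for rec in site_records:
        site_rows.setdefault(rec.cohort_id, []).append(rec)

    conflicts: list[IdentifierConflict] = []
    eligible: list[EligibleRecord] = []
    for cohort_id in sorted(set(central_by_id) & set(site_rows)):
        rows = site_rows[cohort_id]
        head = rows[0]
        for other in rows[1:]:
            for fld in _IDENTIFIER_FIELDS:
                kept, new = getattr(head, fld), getattr(other, fld)
                if kept != new:
                    conflicts.append(
                        IdentifierConflict(cohort_id, fld, kept, new, other.site_id)
                    )
        eligible.append(
            EligibleRecord(
                cohort_id=cohort_id,
                site_id=head.site_id,
                site_ids=tuple(dict.fromkeys(r.site_id for r in rows)),
                first_name=head.first_name,
                last_name=head.last_name,
                dob=head.dob,
                ssn=head.ssn,
                birth_sex=head.birth_sex,
                central=central_by_id[cohort_id],
            )
        )

    central_only = sorted(set(central_by_id) - set(site_rows))
    site_only = sorted(set(site_rows) - set(central_by_id))
    return FilterOutcome(
        eligible=eligible,
        central_only_ids=central_only,
        site_only_ids=site_only,
        conflicts=conflicts,
    )
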