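"""Report suite: recipient-redacted match reports, demographics discrepancy
comparison, lab comparison with lab-group coding, lab-site, opportunistic
infection, treatment and filter reports.

Two recipients exist.  The registry side (``health_dept``) is authorized to
view protected health information and receives full reports with matching
identifiers.  The cohort study team (``cohort``) is not: its reports never
carry names, DOB, SSN or the registry person identifier — for matched
participants the cohort sees only the Cohort ID and the matching score.

Lab records are compared by sample date, lab type, result and result
interpretation and coded into a *lab group* describing how many of those
variables agreed; labs dated on or before the cohort consent date are
excluded from the comparison entirely.  Result equality is exact after
canonicalization (trailing zeros trimmed); recording-convention differences
are expressed through the codes, not a numeric tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dedup import PersonCluster
from .filter_stage import FilterOutcome
from .match_engine import MatchResult
from .records import DemographicProfile, LabRecord

__all__ = [
    "RECIPIENTS",
    "LAB_GROUP_CODES",
    "DemographicDiscrepancy",
    "LabComparison",
    "RedactionError",
    "ConfigurationError",
    "DEFAULT_DEMOGRAPHIC_FIELDS",
    "compare_demographics",
    "compare_labs",
    "build_report",
    "format_percent",
    "REPORT_KINDS",
]

RECIPIENTS = ("cohort", "health_dept")

# lab-group codes, one per compared lab record per direction
DUPLICATE = "DUPLICATE"
RESULT_INTERP_DIFF = "RESULT_INTERP_DIFF"
RESULT_DIFF = "RESULT_DIFF"
NEW = "NEW"
LAB_GROUP_CODES = (DUPLICATE, RESULT_INTERP_DIFF, RESULT_DIFF, NEW)

# column names that must never reach the cohort recipient
_PHI_COLUMNS = frozenset(
    {"person_id", "first_name", "last_name", "dob", "ssn", "birth_sex", "aliases"}
)

DEFAULT_DEMOGRAPHIC_FIELDS = (
    "vital_status",
    "gender",
    "sex_at_birth",
    "race",
    "hiv_transmission_risk",
    "state_of_residence",
    "hiv_diagnosis_date",
    "aids_diagnosis_date",
)


class RedactionError(PermissionError):
    """A report containing protected identifiers was requested for the cohort."""


class ConfigurationError(ValueError):
    """Unknown report kind, recipient, or demographic field."""


def format_percent(numerator: int, denominator: int) -> str:
    """Percentage formatted round-half-up to one decimal, e.g. ``'93.0'``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Demographics comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicDiscrepancy:
    cohort_id: str
    field: str
    cohort_value: object
    surveillance_value: object
    kind: str  # missing_in_cohort | missing_in_surveillance | conflict | absent_field


_ABSENT = object()  # attribute not present in one side's schema


def _canonical(value):
    if value is None or value is _ABSENT:
        return None
    if isinstance(value, date):
        return value
    return str(value).strip().casefold() or None


def compare_demographics(
    cohort_profile,
    surv_profile,
    fields: Sequence[str] = DEFAULT_DEMOGRAPHIC_FIELDS,
    *,
    cohort_id: str = "",
) -> list[DemographicDiscrepancy]:
    """One discrepancy row per field that is missing or unequal after
    canonicalization; fully concordant fields produce no row.

    Canonicalization is case- and whitespace-insensitive for string fields
    and exact for dates.  A field name absent from
    :class:`~linkbox.records.DemographicProfile` raises
    :class:`ConfigurationError` unless one side simply lacks the attribute,
    which yields an ``absent_field`` row.
    """
    known = {f.name for f in DemographicProfile.__dataclass_fields__.values()} \
        if hasattr(DemographicProfile, "__dataclass_fields__") else set()
    out: list[DemographicDiscrepancy] = []
    for field_name in fields:
        has_c = hasattr(cohort_profile, field_name)
        has_s = hasattr(surv_profile, field_name)
        if not has_c and not has_s:
            raise ConfigurationError(f"unknown demographic field {field_name!r}")
        if field_name not in known and not (has_c and has_s):
            raise ConfigurationError(f"unknown demographic field {field_name!r}")
        c_val = getattr(cohort_profile, field_name, _ABSENT)
        s_val = getattr(surv_profile, field_name, _ABSENT)
        if c_val is _ABSENT or s_val is _ABSENT:
            out.append(
                DemographicDiscrepancy(
                    cohort_id, field_name,
                    None if c_val is _ABSENT else c_val,
                    None if s_val is _ABSENT else s_val,
                    "absent_field",
                )
            )
            continue
        c_canon, s_canon = _canonical(c_val), _canonical(s_val)
        if c_canon == s_canon:
            continue
        if c_canon is None:
            kind = "missing_in_cohort"
        elif s_canon is None:
            kind = "missing_in_surveillance"
        else:
            kind = "conflict"
        out.append(DemographicDiscrepancy(cohort_id, field_name, c_val, s_val, kind))
    return out


# ---------------------------------------------------------------------------
# Lab comparison
# ---------------------------------------------------------------------------


@dataclass
class LabComparison:
    coded_pairs: list[tuple[LabRecord, LabRecord, str]]  # (cohort, surveillance, code)
    new_to_cohort: list[LabRecord]  # surveillance-only labs
    new_to_surveillance: list[LabRecord]  # cohort-only labs


def _canonical_result(result: Decimal) -> Decimal:
    """Trim trailing zeros so 200.0 equals 200."""
    normalized = result.normalize()
    # Decimal('2E+2') round-trips oddly; re-quantize integers
    if normalized == normalized.to_integral_value():
        normalized = normalized.quantize(Decimal(1))
    return normalized


def _lab_sort_key(lab: LabRecord):
    return (_canonical_result(lab.result), lab.interpretation or "")


def _code_pair(cohort_lab: LabRecord, surv_lab: LabRecord) -> str:
    if _canonical_result(cohort_lab.result) != _canonical_result(surv_lab.result):
        return RESULT_DIFF
    if (cohort_lab.interpretation or None) != (surv_lab.interpretation or None):
        return RESULT_INTERP_DIFF
    return DUPLICATE


def compare_labs(
    cohort_labs: Iterable[LabRecord],
    surv_labs: Iterable[LabRecord],
    consent_date: Optional[date],
) -> LabComparison:
    """Pair and code lab records for one matched participant.

    Labs dated on or before ``consent_date`` are dropped before any
    comparison (lab records must occur strictly after consent).  Remaining
    labs are paired greedily within each (sample_date, lab_type) group in
    result-sorted order and coded DUPLICATE / RESULT_INTERP_DIFF /
    RESULT_DIFF; unpaired labs are NEW to the side lacking them.
    """

    def after_consent(labs):
        return [
            lab for lab in labs
            if consent_date is None or lab.sample_date > consent_date
        ]

    c_groups: dict[tuple, list[LabRecord]] = {}
    for lab in after_consent(cohort_labs):
        c_groups.setdefault((lab.sample_date, lab.lab_type), []).append(lab)
    s_groups: dict[tuple, list[LabRecord]] = {}
    for lab in after_consent(surv_labs):
        s_groups.setdefault((lab.sample_date, lab.lab_type), []).append(lab)

    coded: list[tuple[LabRecord, LabRecord, str]] = []
    new_to_cohort: list[LabRecord] = []
    new_to_surveillance: list[LabRecord] = []

    for key in sorted(set(c_groups) | set(s_groups)):
        c_list = sorted(c_groups.get(key, []), key=_lab_sort_key)
        s_list = sorted(s_groups.get(key, []), key=_lab_sort_key)
        for c_lab, s_lab in zip(c_list, s_list):
            coded.append((c_lab, s_lab, _code_pair(c_lab, s_lab)))
        new_to_surveillance.extend(c_list[len(s_list):])
        new_to_cohort.extend(s_list[len(c_list):])

    return LabComparison(coded, new_to_cohort, new_to_surveillance)


# ---------------------------------------------------------------------------
# Report builders
# ---------------------------------------------------------------------------


def _require(inputs: Mapping, *names):
    missing = [n for n in names if n not in inputs]
    if missing:
        raise ConfigurationError(f"report inputs missing {missing}")
    return [inputs[n] for n in names]


def _match_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    (results,) = _require(inputs, "results")
    rows = []
    eligible_by_id = inputs.get("eligible_by_id", {})
    for r in results:
        if recipient == "cohort":
            rows.append({"cohort_id": r.cohort_id, "score": r.score})
        else:
            rec = eligible_by_id.get(r.cohort_id)
            rows.append(
                {
                    "cohort_id": r.cohort_id,
                    "person_id": r.person_id,
                    "score": r.score,
                    "level": r.level_description,
                    "name_source": r.name_source,
                    "shared": r.shared,
                    "tie_flag": r.tie_flag,
                    "first_name": rec.first_name if rec else None,
                    "last_name": rec.last_name if rec else None,
                    "dob": rec.dob.isoformat() if rec and rec.dob else None,
                    "ssn": rec.ssn if rec else None,
                    "birth_sex": rec.birth_sex if rec else None,
                }
            )
    columns = (
        ["cohort_id", "score"]
        if recipient == "cohort"
        else [
            "cohort_id", "person_id", "score", "level", "name_source", "shared",
            "tie_flag", "first_name", "last_name", "dob", "ssn", "birth_sex",
        ]
    )
    return pd.DataFrame(rows, columns=columns)


def _unmatched_ids(inputs: Mapping) -> list[str]:
    eligible, results = _require(inputs, "eligible", "results")
    matched = {r.cohort_id for r in results}
    return sorted(e.cohort_id for e in eligible if e.cohort_id not in matched)


def _unmatched_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    return pd.DataFrame({"cohort_id": _unmatched_ids(inputs)}, dtype=object)


def _cohort_unmatched_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    (outcome,) = _require(inputs, "filter_outcome")
    rows = [
        {"cohort_id": cid, "reason": "not_in_site_files"}
        for cid in outcome.central_only_ids
    ]
    rows += [
        {"cohort_id": cid, "reason": "no_surveillance_match"}
        for cid in _unmatched_ids(inputs)
    ]
    frame = pd.DataFrame(rows, columns=["cohort_id", "reason"])
    return frame.sort_values(["cohort_id"], kind="stable").reset_index(drop=True)


def _multi_site_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    (clusters,) = _require(inputs, "clusters")
    rows = []
    for cluster in clusters:
        if cluster.size < 2:
            continue
        row = {
            "cohort_ids": ";".join(cluster.cohort_ids),
            "n_cohort_ids": cluster.size,
            "sites": ";".join(cluster.sites),
        }
        if recipient == "health_dept":
            row = {"person_id": cluster.person_id, **row, "best_score": cluster.best_score}
        rows.append(row)
    columns = (
        ["cohort_ids", "n_cohort_ids", "sites"]
        if recipient == "cohort"
        else ["person_id", "cohort_ids", "n_cohort_ids", "sites", "best_score"]
    )
    return pd.DataFrame(rows, columns=columns)


def _shared_pairs(inputs: Mapping):
    """Yield (result, eligible record, surveillance record) for shared matches."""
    results, eligible_by_id, surveillance_by_id = _require(
        inputs, "results", "eligible_by_id", "surveillance_by_id"
    )
    for r in results:
        if r.shared:
            yield r, eligible_by_id[r.cohort_id], surveillance_by_id[r.person_id]


def _demographics_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    fields = inputs.get("fields", DEFAULT_DEMOGRAPHIC_FIELDS)
    rows = []
    for r, rec, surv in _shared_pairs(inputs):
        for disc in compare_demographics(
            rec.central.demographics, surv.demographics, fields, cohort_id=r.cohort_id
        ):
            rows.append(
                {
                    "cohort_id": disc.cohort_id,
                    "field": disc.field,
                    "cohort_value": _fmt_cell(disc.cohort_value),
                    "surveillance_value": _fmt_cell(disc.surveillance_value),
                    "kind": disc.kind,
                }
            )
    return pd.DataFrame(
        rows, columns=["cohort_id", "field", "cohort_value", "surveillance_value", "kind"]
    )


def _fmt_cell(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, date):
        return value.isoformat()
    return str(value)


def _labs_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    rows = []
    for r, rec, surv in _shared_pairs(inputs):
        comparison = compare_labs(rec.central.labs, surv.labs, rec.central.consent_date)
        for c_lab, s_lab, code in comparison.coded_pairs:
            rows.append(
                {
                    "cohort_id": r.cohort_id,
                    "sample_date": c_lab.sample_date.isoformat(),
                    "lab_type": c_lab.lab_type,
                    "cohort_result": str(c_lab.result),
                    "cohort_interpretation": c_lab.interpretation,
                    "surveillance_result": str(s_lab.result),
                    "surveillance_interpretation": s_lab.interpretation,
                    "lab_group": code,
                    "new_to": None,
                }
            )
        for lab, new_to in [
            *((lab, "cohort") for lab in comparison.new_to_cohort),
            *((lab, "surveillance") for lab in comparison.new_to_surveillance),
        ]:
            cohort_side = new_to == "surveillance"
            rows.append(
                {
                    "cohort_id": r.cohort_id,
                    "sample_date": lab.sample_date.isoformat(),
                    "lab_type": lab.lab_type,
                    "cohort_result": str(lab.result) if cohort_side else None,
                    "cohort_interpretation": lab.interpretation if cohort_side else None,
                    "surveillance_result": None if cohort_side else str(lab.result),
                    "surveillance_interpretation": None if cohort_side else lab.interpretation,
                    "lab_group": NEW,
                    "new_to": new_to,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort_id", "sample_date", "lab_type", "cohort_result",
            "cohort_interpretation", "surveillance_result",
            "surveillance_interpretation", "lab_group", "new_to",
        ],
    )


def _lab_site_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    rows = []
    for r, rec, surv in _shared_pairs(inputs):
        consent = rec.central.consent_date
        counts: dict[str, int] = {}
        for lab in surv.labs:
            if consent is not None and lab.sample_date <= consent:
                continue
            if lab.facility:
                counts[lab.facility] = counts.get(lab.facility, 0) + 1
        for facility in sorted(counts):
            rows.append(
                {"cohort_id": r.cohort_id, "facility": facility, "n_labs": counts[facility]}
            )
    return pd.DataFrame(rows, columns=["cohort_id", "facility", "n_labs"])


def _oi_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    rows = []
    for r, _rec, surv in _shared_pairs(inputs):
        for condition, when in surv.opportunistic_infections:
            rows.append(
                {
                    "cohort_id": r.cohort_id,
                    "condition": condition,
                    "date": when.isoformat() if when else None,
                }
            )
    return pd.DataFrame(rows, columns=["cohort_id", "condition", "date"])


def _treatment_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    if recipient != "health_dept":
        raise RedactionError("the treatment report is restricted to the health department")
    rows = []
    for r, rec, _surv in _shared_pairs(inputs):
        for drug, start, end in rec.central.treatments:
            rows.append(
                {
                    "cohort_id": r.cohort_id,
                    "person_id": r.person_id,
                    "drug": drug,
                    "start_date": start.isoformat(),
                    "end_date": end.isoformat() if end else None,
                }
            )
    return pd.DataFrame(
        rows, columns=["cohort_id", "person_id", "drug", "start_date", "end_date"]
    )


def _filter_report(recipient: str, inputs: Mapping) -> pd.DataFrame:
    (outcome,) = _require(inputs, "filter_outcome")
    rows = [
        {"cohort_id": cid, "missing_from": "site_files"}
        for cid in outcome.central_only_ids
    ] + [
        {"cohort_id": cid, "missing_from": "central_file"}
        for cid in outcome.site_only_ids
    ]
    return pd.DataFrame(rows, columns=["cohort_id", "missing_from"])


_BUILDERS = {
    "match": _match_report,
    "unmatched": _unmatched_report,
    "cohort_unmatched": _cohort_unmatched_report,
    "multi_site": _multi_site_report,
    "demographics": _demographics_report,
    "labs": _labs_report,
    "lab_site": _lab_site_report,
    "oi": _oi_report,
    "treatment": _treatment_report,
    "filter": _filter_report,
}

REPORT_KINDS = tuple(_BUILDERS)

# report kinds a given recipient may receive
_RECIPIENT_KINDS = {
    "cohort": (
        "match", "unmatched", "cohort_unmatched", "multi_site", "demographics",
        "labs", "lab_site", "oi", "filter",
    ),
    "health_dept": (
        "match", "unmatched", "multi_site", "demographics", "labs", "treatment",
        "filter",
    ),
}


def recipient_kinds(recipient: str) -> tuple[str, ...]:
    """Report kinds deliverable to a recipient."""
    try:
        return _RECIPIENT_KINDS[recipient]
    except KeyError:
        raise ConfigurationError(f"unknown recipient {recipient!r}") from None


def build_report(kind: str, recipient: str, inputs: Mapping) -> pd.DataFrame:
    """Build one report table for one recipient.

    ``inputs`` supplies the pipeline objects the kind needs: ``results``
    (match output), ``eligible`` / ``eligible_by_id`` (merged records),
    ``surveillance_by_id``, ``clusters``, ``filter_outcome`` and optional
    ``fields`` for the demographics report.  Cohort-recipient tables are
    verified to contain no identifier columns before being returned.
    """
    if recipient not in RECIPIENTS:
        raise ConfigurationError(f"unknown recipient {recipient!r}")
    try:
        builder = _BUILDERS[kind]
    except KeyError:
        raise ConfigurationError(f"unknown report kind {kind!r}") from None
    frame = builder(recipient, inputs)
    if recipient == "cohort":
        leaked = _PHI_COLUMNS & set(frame.columns)
        if leaked:
            raise RedactionError(
                f"report {kind!r} would expose {sorted(leaked)} to the cohort"
            )
    return frame
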