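"""Domain record types, CSV readers/writers, and template-driven file verification.

Three delimited feeds are exchanged:

* **site** files — one row per enrollment at a clinic site, carrying the
  matching identifiers (name, date of birth, Social Security number, birth
  sex) keyed by the study-assigned Cohort ID;
* the **central** cohort file — a limited dataset without direct identifiers:
  demographics, consent date, labs and antiretroviral treatments per
  Cohort ID;
* the **surveillance** file — a person-view analog of an HIV registry, with
  alias names, labs (with reporting facility), opportunistic infections and
  vital status per registry person.

Files are RFC 4180 comma-separated UTF-8 with a header row.  Dates are
ISO 8601 (``YYYY-MM-DD``); anything else is a verification issue.  Missing
is the empty cell on disk and ``None`` in memory — never the empty string.
SSNs are stored digits-only (hyphens stripped on read) and must have 9
digits (full) or 4 (partial); other lengths are treated as missing with a
warning.  Nested payloads (aliases, labs, treatments, opportunistic
infections) live in semicolon-delimited subfields, e.g. aliases as
``"LAST1,FIRST1;LAST2,FIRST2"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "LabRecord",
    "DemographicProfile",
    "SiteRecord",
    "CentralRecord",
    "SurveillanceRecord",
    "Issue",
    "ReadResult",
    "SchemaError",
    "KeyCollisionError",
    "read_table",
    "write_table",
    "verify_file",
    "SCHEMAS",
]

MISSING_TOKEN = ""  # on-disk encoding of a missing value

LAB_TYPES = frozenset({"CD4_count", "CD4_percent", "viral_load"})
INTERPRETATIONS = frozenset({"EQ", "LT", "GT", "UNDETECTABLE"})
VITAL_STATUSES = frozenset({"alive", "deceased", "unknown"})
BIRTH_SEXES = frozenset({"M", "F", "unknown"})


class SchemaError(ValueError):
    """A required column is absent or the schema name is unknown."""


class KeyCollisionError(ValueError):
    """Two rows in one file share the unique key."""

    def __init__(self, schema_name: str, keys: Sequence[object]):
        self.keys = list(keys)
        super().__init__(
            f"duplicate keys in {schema_name} file: "
            + ", ".join(repr(k) for k in self.keys)
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabRecord:
    """One laboratory result (CD4 count, CD4 percentage, or viral load)."""

    sample_date: date
    lab_type: str
    result: Decimal
    interpretation: Optional[str] = None  # EQ, LT, GT, UNDETECTABLE or None
    facility: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lab_type not in LAB_TYPES:
            raise ValueError(f"unknown lab_type {self.lab_type!r}")
        if self.result < 0:
            raise ValueError("lab result must be non-negative")
        if self.lab_type == "CD4_percent" and not 0 <= self.result <= 100:
            raise ValueError("CD4_percent must lie in [0, 100]")
        if self.interpretation is not None and self.interpretation not in INTERPRETATIONS:
            raise ValueError(f"unknown interpretation {self.interpretation!r}")


@dataclass(frozen=True)
class DemographicProfile:
    """Demographic payload compared between the two entities after a match."""

    vital_status: Optional[str] = None
    gender: Optional[str] = None
    sex_at_birth: Optional[str] = None
    race: Optional[str] = None
    hiv_transmission_risk: Optional[str] = None
    state_of_residence: Optional[str] = None
    hiv_diagnosis_date: Optional[date] = None
    aids_diagnosis_date: Optional[date] = None


@dataclass(frozen=True)
class SiteRecord:
    """Identifying record submitted by a clinic site, keyed by Cohort ID."""

    cohort_id: str
    site_id: str
    first_name: Optional[str]
    last_name: Optional[str]
    dob: Optional[date]
    ssn: Optional[str]  # digits only, length 9 (full) or 4 (partial)
    birth_sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.cohort_id:
            raise ValueError("cohort_id must be non-empty")
        if self.ssn is not None and not (
            self.ssn.isdigit() and len(self.ssn) in (4, 9)
        ):
            raise ValueError(f"ssn must be 9 or 4 digits, got {self.ssn!r}")
        if self.birth_sex not in BIRTH_SEXES:
            raise ValueError(f"birth_sex must be one of {sorted(BIRTH_SEXES)}")


@dataclass(frozen=True)
class CentralRecord:
    """Deidentified central-repository record for one Cohort ID."""

    cohort_id: str
    consent_date: Optional[date]
    demographics: DemographicProfile = field(default_factory=DemographicProfile)
    labs: tuple[LabRecord, ...] = ()
    treatments: tuple[tuple[str, date, Optional[date]], ...] = ()

    def __post_init__(self) -> None:
        if not self.cohort_id:
            raise ValueError("cohort_id must be non-empty")


@dataclass(frozen=True)
class SurveillanceRecord:
    """Registry person-view with alias names, labs, OIs and vital status."""

    person_id: str
    first_name: Optional[str]
    last_name: Optional[str]
    aliases: tuple[tuple[Optional[str], Optional[str]], ...] = ()  # (first, last)
    dob: Optional[date] = None
    ssn: Optional[str] = None
    birth_sex: str = "unknown"
    prior_cohort_id: Optional[str] = None
    demographics: DemographicProfile = field(default_factory=DemographicProfile)
    labs: tuple[LabRecord, ...] = ()
    opportunistic_infections: tuple[tuple[str, Optional[date]], ...] = ()
    vital_status: str = "unknown"
    death_date: Optional[date] = None
    cause_of_death: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.person_id:
            raise ValueError("person_id must be non-empty")
        for first, last in self.aliases:
            if not (first or last):
                raise ValueError("alias must have at least one non-empty name part")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"vital_status must be one of {sorted(VITAL_STATUSES)}")
        if self.death_date is not None and self.vital_status != "deceased":
            raise ValueError("death_date present implies vital_status == 'deceased'")


# ---------------------------------------------------------------------------
# Verification issues and read results
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Issue:
    """One verification finding: 1-based data row (0 = file level), field, text."""

    row: int
    field: str
    issue: str


@dataclass
class ReadResult:
    records: list
    warnings: list[Issue]


# ---------------------------------------------------------------------------
# Field-level parsers.  Each returns (value, issue-text-or-None); a parse
# failure yields an explicit missing value plus a warning, never an exception.
# ---------------------------------------------------------------------------


def _parse_str(raw: str) -> tuple[Optional[str], Optional[str]]:
    raw = raw.strip()
    return (raw or None), None


def _parse_date(raw: str, *, no_future: bool = False) -> tuple[Optional[date], Optional[str]]:
    raw = raw.strip()
    if not raw:
        return None, None
    try:
        value = date.fromisoformat(raw)
    except ValueError:
        return None, f"not an ISO 8601 date: {raw!r}"
    if no_future and value > date.today():
        return None, f"date in the future: {raw!r}"
    return value, None


def _parse_ssn(raw: str) -> tuple[Optional[str], Optional[str]]:
    raw = raw.strip().replace("-", "")
    if not raw:
        return None, None
    if not raw.isdigit():
        return None, f"ssn contains non-digits: {raw!r}"
    if len(raw) not in (4, 9):
        return None, f"ssn must have 9 or 4 digits, got {len(raw)}"
    return raw, None


def _parse_birth_sex(raw: str) -> tuple[str, Optional[str]]:
    raw = raw.strip().upper()
    if not raw or raw == "UNKNOWN":
        return "unknown", None
    if raw in ("M", "F"):
        return raw, None
    return "unknown", f"unknown birth_sex code: {raw!r}"


def _parse_vital_status(raw: str) -> tuple[str, Optional[str]]:
    raw = raw.strip().lower()
    if not raw or raw == "unknown":
        return "unknown", None
    if raw in VITAL_STATUSES:
        return raw, None
    return "unknown", f"unknown vital_status: {raw!r}"


def _parse_decimal(raw: str) -> tuple[Optional[Decimal], Optional[str]]:
    raw = raw.strip()
    if not raw:
        return None, None
    try:
        return Decimal(raw), None
    except InvalidOperation:
        return None, f"not a number: {raw!r}"


def _parse_aliases(raw: str) -> tuple[tuple, Optional[str]]:
    """Parse ``"LAST1,FIRST1;LAST2,FIRST2"`` into ((first, last), ...)."""
    raw = raw.strip()
    if not raw:
        return (), None
    out = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        last, _, first = chunk.partition(",")
        first, last = first.strip() or None, last.strip() or None
        if not (first or last):
            return (), f"alias with no name parts: {chunk!r}"
        out.append((first, last))
    return tuple(out), None


def _parse_labs(raw: str) -> tuple[tuple[LabRecord, ...], Optional[str]]:
    """Parse ``"date|type|result|interp|facility;..."`` lab subfields."""
    raw = raw.strip()
    if not raw:
        return (), None
    out = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split("|")
        if len(parts) < 3:
            return (), f"malformed lab subfield: {chunk!r}"
        parts += [""] * (5 - len(parts))
        sample_date, err = _parse_date(parts[0])
        if err or sample_date is None:
            return (), err or f"lab missing sample date: {chunk!r}"
        result, err = _parse_decimal(parts[2])
        if err or result is None:
            return (), err or f"lab missing result: {chunk!r}"
        interp = parts[3].strip().upper() or None
        if interp is not None and interp not in INTERPRETATIONS:
            return (), f"unknown lab interpretation: {parts[3]!r}"
        try:
            out.append(
                LabRecord(
                    sample_date=sample_date,
                    lab_type=parts[1].strip(),
                    result=result,
                    interpretation=interp,
                    facility=parts[4].strip() or None,
                )
            )
        except ValueError as exc:
            return (), str(exc)
    return tuple(out), None


def _parse_treatments(raw: str) -> tuple[tuple, Optional[str]]:
    """Parse ``"drug|start|end;..."`` treatment subfields."""
    raw = raw.strip()
    if not raw:
        return (), None
    out = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split("|")
        parts += [""] * (3 - len(parts))
        drug = parts[0].strip()
        if not drug:
            return (), f"treatment with no drug name: {chunk!r}"
        start, err = _parse_date(parts[1])
        if err or start is None:
            return (), err or f"treatment missing start date: {chunk!r}"
        end, err = _parse_date(parts[2])
        if err:
            return (), err
        out.append((drug, start, end))
    return tuple(out), None


def _parse_ois(raw: str) -> tuple[tuple, Optional[str]]:
    """Parse ``"condition|date;..."`` opportunistic-infection subfields."""
    raw = raw.strip()
    if not raw:
        return (), None
    out = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        cond, _, when = chunk.partition("|")
        cond = cond.strip()
        if not cond:
            return (), f"opportunistic infection with no condition: {chunk!r}"
        parsed, err = _parse_date(when)
        if err:
            return (), err
        out.append((cond, parsed))
    return tuple(out), None


# ---------------------------------------------------------------------------
# Schemas: column order for writing, required columns, row -> record builders
# ---------------------------------------------------------------------------

_DEMOG_COLUMNS = [
    "vital_status",
    "gender",
    "sex_at_birth",
    "race",
    "hiv_transmission_risk",
    "state_of_residence",
    "hiv_diagnosis_date",
    "aids_diagnosis_date",
]

SITE_COLUMNS = ["cohort_id", "site_id", "first_name", "last_name", "dob", "ssn", "birth_sex"]
CENTRAL_COLUMNS = ["cohort_id", "consent_date", *_DEMOG_COLUMNS, "labs", "treatments"]
SURVEILLANCE_COLUMNS = [
    "person_id",
    "first_name",
    "last_name",
    "aliases",
    "dob",
    "ssn",
    "birth_sex",
    "prior_cohort_id",
    *_DEMOG_COLUMNS,
    "labs",
    "opportunistic_infections",
    "death_date",
    "cause_of_death",
]


def _build_demographics(row: dict, rownum: int, issues: list[Issue]) -> DemographicProfile:
    values: dict = {}
    for col in _DEMOG_COLUMNS:
        raw = row.get(col, "")
        if col.endswith("_date"):
            values[col], err = _parse_date(raw)
        elif col == "vital_status":
            values[col], err = _parse_vital_status(raw)
            if values[col] == "unknown":
                values[col] = None
        else:
            values[col], err = _parse_str(raw)
        if err:
            issues.append(Issue(rownum, col, err))
    return DemographicProfile(**values)


def _field(row, col, parser, rownum, issues, **kw):
    value, err = parser(row.get(col, ""), **kw) if kw else parser(row.get(col, ""))
    if err:
        issues.append(Issue(rownum, col, err))
    return value


def _build_site(row: dict, rownum: int, issues: list[Issue]) -> Optional[SiteRecord]:
    cohort_id = row.get("cohort_id", "").strip()
    if not cohort_id:
        issues.append(Issue(rownum, "cohort_id", "cohort_id is empty"))
        return None
    return SiteRecord(
        cohort_id=cohort_id,
        site_id=row.get("site_id", "").strip(),
        first_name=_field(row, "first_name", _parse_str, rownum, issues),
        last_name=_field(row, "last_name", _parse_str, rownum, issues),
        dob=_field(row, "dob", _parse_date, rownum, issues, no_future=True),
        ssn=_field(row, "ssn", _parse_ssn, rownum, issues),
        birth_sex=_field(row, "birth_sex", _parse_birth_sex, rownum, issues),
    )


def _build_central(row: dict, rownum: int, issues: list[Issue]) -> Optional[CentralRecord]:
    cohort_id = row.get("cohort_id", "").strip()
    if not cohort_id:
        issues.append(Issue(rownum, "cohort_id", "cohort_id is empty"))
        return None
    return CentralRecord(
        cohort_id=cohort_id,
        consent_date=_field(row, "consent_date", _parse_date, rownum, issues),
        demographics=_build_demographics(row, rownum, issues),
        labs=_field(row, "labs", _parse_labs, rownum, issues),
        treatments=_field(row, "treatments", _parse_treatments, rownum, issues),
    )


def _build_surveillance(row: dict, rownum: int, issues: list[Issue]) -> Optional[SurveillanceRecord]:
    person_id = row.get("person_id", "").strip()
    if not person_id:
        issues.append(Issue(rownum, "person_id", "person_id is empty"))
        return None
    vital, err = _parse_vital_status(row.get("vital_status", ""))
    if err:
        issues.append(Issue(rownum, "vital_status", err))
    death_date = _field(row, "death_date", _parse_date, rownum, issues)
    if death_date is not None and vital != "deceased":
        issues.append(
            Issue(rownum, "death_date", "death_date present but vital_status is not 'deceased'")
        )
        death_date = None
    demog = _build_demographics(row, rownum, issues)
    demog = replace(demog, vital_status=vital if vital != "unknown" else demog.vital_status)
    return SurveillanceRecord(
        person_id=person_id,
        first_name=_field(row, "first_name", _parse_str, rownum, issues),
        last_name=_field(row, "last_name", _parse_str, rownum, issues),
        aliases=_field(row, "aliases", _parse_aliases, rownum, issues),
        dob=_field(row, "dob", _parse_date, rownum, issues, no_future=True),
        ssn=_field(row, "ssn", _parse_ssn, rownum, issues),
        birth_sex=_field(row, "birth_sex", _parse_birth_sex, rownum, issues),
        prior_cohort_id=_field(row, "prior_cohort_id", _parse_str, rownum, issues),
        demographics=demog,
        labs=_field(row, "labs", _parse_labs, rownum, issues),
        opportunistic_infections=_field(
            row, "opportunistic_infections", _parse_ois, rownum, issues
        ),
        vital_status=vital,
        death_date=death_date,
        cause_of_death=_field(row, "cause_of_death", _parse_str, rownum, issues),
    )


@dataclass(frozen=True)
class _Schema:
    name: str
    columns: tuple[str, ...]
    required: tuple[str, ...]
    key: callable  # record -> unique key
    build: callable  # (row dict, rownum, issues) -> record or None


SCHEMAS = {
    "site": _Schema(
        "site",
        tuple(SITE_COLUMNS),
        ("cohort_id", "site_id"),
        lambda r: (r.cohort_id, r.site_id),
        _build_site,
    ),
    "central": _Schema(
        "central",
        tuple(CENTRAL_COLUMNS),
        ("cohort_id",),
        lambda r: r.cohort_id,
        _build_central,
    ),
    "surveillance": _Schema(
        "surveillance",
        tuple(SURVEILLANCE_COLUMNS),
        ("person_id",),
        lambda r: r.person_id,
        _build_surveillance,
    ),
}


def _get_schema(schema_name: str) -> _Schema:
    try:
        return SCHEMAS[schema_name]
    except KeyError:
        raise SchemaError(
            f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}"
        ) from None


# ---------------------------------------------------------------------------
# Readers / writers / verification
# ---------------------------------------------------------------------------


def _scan(path, schema: _Schema, column_map=None):
    """Yield (records, issues, schema_issues, duplicate_keys) for one file.

    ``column_map`` optionally renames raw file columns to schema columns
    (raw name -> schema name) before any checks.
    """
    column_map = dict(column_map or {})
    records: list = []
    issues: list[Issue] = []
    schema_issues: list[Issue] = []
    seen: dict = {}
    duplicates: list = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = [column_map.get(c, c) for c in (reader.fieldnames or [])]
        missing_cols = [c for c in schema.required if c not in header]
        if missing_cols:
            for col in missing_cols:
                schema_issues.append(Issue(0, col, f"missing required column {col!r}"))
            return records, issues, schema_issues, duplicates
        for rownum, row in enumerate(reader, start=1):
            row = {
                column_map.get(k, k): (v if v is not None else "")
                for k, v in row.items()
                if k
            }
            record = schema.build(row, rownum, issues)
            if record is None:
                continue
            key = schema.key(record)
            if key in seen:
                duplicates.append(key)
                issues.append(Issue(rownum, schema.required[0], f"duplicate key {key!r}"))
                continue
            seen[key] = rownum
            records.append(record)
    return records, issues, schema_issues, duplicates


def read_table(path, schema_name: str, column_map=None) -> ReadResult:
    """Read one delimited feed into typed records.

    Unparseable fields become explicit missing values and are recorded in the
    result's warning list.  A missing required column raises
    :class:`SchemaError`; a repeated unique key raises
    :class:`KeyCollisionError`.  ``column_map`` renames raw columns to schema
    columns first.
    """
    schema = _get_schema(schema_name)
    records, issues, schema_issues, duplicates = _scan(path, schema, column_map)
    if schema_issues:
        raise SchemaError("; ".join(i.issue for i in schema_issues))
    if duplicates:
        raise KeyCollisionError(schema_name, duplicates)
    return ReadResult(records=records, warnings=sorted(issues))


def verify_file(path, schema_name: str, column_map=None) -> list[Issue]:
    """Check one file against its schema template without raising.

    Returns a deterministic report sorted by (row, field); the report is
    empty exactly when :func:`read_table` would succeed with zero warnings.
    Row 0 marks file-level issues (e.g. a missing column).
    """
    schema = _get_schema(schema_name)
    _, issues, schema_issues, _ = _scan(path, schema, column_map)
    return sorted(schema_issues + issues)


def write_verification_report(issues: Iterable[Issue], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["row", "field", "issue"])
        for issue in issues:
            writer.writerow([issue.row, issue.field, issue.issue])


# -- serialization back to CSV ----------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, date):
        return value.isoformat()
    return str(value)


def _fmt_labs(labs: Sequence[LabRecord]) -> str:
    return ";".join(
        "|".join(
            [
                lab.sample_date.isoformat(),
                lab.lab_type,
                str(lab.result),
                lab.interpretation or "",
                lab.facility or "",
            ]
        )
        for lab in labs
    )


def _site_row(r: SiteRecord) -> list[str]:
    return [
        r.cohort_id,
        r.site_id,
        _fmt(r.first_name),
        _fmt(r.last_name),
        _fmt(r.dob),
        _fmt(r.ssn),
        r.birth_sex if r.birth_sex != "unknown" else "",
    ]


def _demog_row(d: DemographicProfile) -> list[str]:
    return [_fmt(getattr(d, col)) for col in _DEMOG_COLUMNS]


def _central_row(r: CentralRecord) -> list[str]:
    treatments = ";".join(
        "|".join([drug, start.isoformat(), end.isoformat() if end else ""])
        for drug, start, end in r.treatments
    )
    return [r.cohort_id, _fmt(r.consent_date), *_demog_row(r.demographics),
            _fmt_labs(r.labs), treatments]


def _surveillance_row(r: SurveillanceRecord) -> list[str]:
    aliases = ";".join(f"{last or ''},{first or ''}" for first, last in r.aliases)
    ois = ";".join(
        f"{cond}|{when.isoformat() if when else ''}"
        for cond, when in r.opportunistic_infections
    )
    demog = replace(r.demographics, vital_status=None)  # carried by the record column
    return [
        r.person_id,
        _fmt(r.first_name),
        _fmt(r.last_name),
        aliases,
        _fmt(r.dob),
        _fmt(r.ssn),
        r.birth_sex if r.birth_sex != "unknown" else "",
        _fmt(r.prior_cohort_id),
        r.vital_status if r.vital_status != "unknown" else "",
        *_demog_row(demog)[1:],
        _fmt_labs(r.labs),
        ois,
        _fmt(r.death_date),
        _fmt(r.cause_of_death),
    ]


_ROW_WRITERS = {"site": _site_row, "central": _central_row, "surveillance": _surveillance_row}


def write_table(records: Iterable, path, schema_name: str) -> None:
    """Write typed records back to CSV; inverse of :func:`read_table`."""
    schema = _get_schema(schema_name)
    to_row = _ROW_WRITERS[schema_name]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(schema.columns)
        for record in records:
            writer.writerow(to_row(record))
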