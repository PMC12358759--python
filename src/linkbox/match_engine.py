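"""Deterministic multi-level match scoring between cohort and registry records.

The matching algorithm is an ordered cascade of levels.  Each level names a
name rule (full first+last name, last name only, last name plus the first
six letters of the first name, or no name requirement) together with a set
of required non-name variables (Cohort ID, date of birth, full SSN, partial
SSN = last 4 digits, birth sex).  A record pair is scored at the
highest-scoring level whose criteria it satisfies; levels with a full-name
rule carry two scores, the higher for agreement with the registry
person-view name and the lower (exactly one less) for agreement with any
alias name.  Scores run from 20 (Cohort ID only) to 100 (full name, DOB,
SSN, birth sex and Cohort ID); pairs scoring at or above the sharing
threshold (61 by default) are eligible for data sharing, while
sub-threshold matches are still reported with ``shared=False``.

All comparisons are exact equality of normalized values: names are
upper-cased with whitespace and punctuation stripped, SSNs are digit
strings, DOB is exact date equality.  There is no phonetic or edit-distance
fuzziness — tolerance to real-world noise comes from the cascade itself
(lower levels need fewer variables) and from alias names, not from
approximate comparison.  A criterion over a field missing on either side is
unsatisfied, never an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

__all__ = [
    "MatchLevel",
    "MatchAlgorithm",
    "MatchResult",
    "normalize_name",
    "default_algorithm",
    "score_pair",
    "generate_candidates",
    "run_match",
    "COHORT_ID",
    "DOB",
    "SSN_FULL",
    "SSN_PARTIAL",
    "BIRTH_SEX",
]

# match variables
COHORT_ID = "COHORT_ID"
DOB = "DOB"
SSN_FULL = "SSN_FULL"
SSN_PARTIAL = "SSN_PARTIAL"
BIRTH_SEX = "BIRTH_SEX"
_VARS = frozenset({COHORT_ID, DOB, SSN_FULL, SSN_PARTIAL, BIRTH_SEX})

# name rules
FULL_NAME = "FULL_NAME"
LAST_ONLY = "LAST_ONLY"
LAST_PLUS_FIRST6 = "LAST_PLUS_FIRST6"
NONE = "NONE"
_NAME_RULES = (FULL_NAME, LAST_ONLY, LAST_PLUS_FIRST6, NONE)

_PUNCT = str.maketrans("", "", " \t\n\r-'.’")


@lru_cache(maxsize=65536)
def normalize_name(raw: Optional[str]) -> Optional[str]:
    """Upper-case and strip whitespace, hyphens, apostrophes and periods.

    Empty or all-punctuation input normalizes to the missing value (None).
    """
    if raw is None:
        return None
    token = raw.translate(_PUNCT).upper()
    return token or None


@dataclass(frozen=True)
class MatchLevel:
    """One row of the scoring cascade."""

    name_rule: str
    required_vars: frozenset
    score_person_view: int
    score_alias: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name_rule not in _NAME_RULES:
            raise ValueError(f"unknown name rule {self.name_rule!r}")
        unknown = set(self.required_vars) - _VARS
        if unknown:
            raise ValueError(f"unknown match variables {sorted(unknown)}")
        if not 20 <= self.score_person_view <= 100:
            raise ValueError("scores must lie in [20, 100]")
        if self.score_alias is not None:
            if self.name_rule != FULL_NAME:
                raise ValueError("alias scores apply to FULL_NAME levels only")
            if self.score_alias != self.score_person_view - 1:
                raise ValueError("alias score must be person-view score minus 1")

    @property
    def description(self) -> str:
        vars_ = "+".join(sorted(self.required_vars)) or "none"
        return f"{self.name_rule}/{vars_}"


def _level(name_rule: str, vars_: Sequence[str], score_pv: int,
           score_alias: Optional[int] = None) -> MatchLevel:
    return MatchLevel(name_rule, frozenset(vars_), score_pv, score_alias)


# The default cascade: 28 levels, scores 20..100, alias variants one point
# below their person-view score.  Frozen as shipped; editable via JSON.
_DEFAULT_LEVELS = (
    _level(FULL_NAME, (COHORT_ID, DOB, SSN_FULL, BIRTH_SEX), 100, 99),
    _level(FULL_NAME, (DOB, SSN_FULL, BIRTH_SEX), 98, 97),
    _level(FULL_NAME, (COHORT_ID, DOB, SSN_PARTIAL, BIRTH_SEX), 95, 94),
    _level(FULL_NAME, (DOB, SSN_PARTIAL, BIRTH_SEX), 93, 92),
    _level(FULL_NAME, (COHORT_ID, DOB, SSN_FULL), 90, 89),
    _level(FULL_NAME, (DOB, SSN_FULL), 88, 87),
    _level(FULL_NAME, (COHORT_ID, DOB, SSN_PARTIAL), 86, 85),
    _level(FULL_NAME, (DOB, SSN_PARTIAL), 84, 83),
    _level(FULL_NAME, (COHORT_ID, DOB, BIRTH_SEX), 82, 81),
    _level(FULL_NAME, (DOB, BIRTH_SEX), 80, 79),
    _level(FULL_NAME, (COHORT_ID, DOB), 78, 77),
    _level(FULL_NAME, (COHORT_ID, SSN_FULL), 76, 75),
    _level(FULL_NAME, (DOB,), 74, 73),
    _level(FULL_NAME, (SSN_FULL,), 72, 71),
    _level(FULL_NAME, (COHORT_ID, SSN_PARTIAL), 70, 69),
    _level(FULL_NAME, (SSN_PARTIAL,), 68, 67),
    _level(LAST_ONLY, (COHORT_ID, DOB, SSN_FULL), 66),
    _level(LAST_ONLY, (DOB, SSN_FULL), 65),
    _level(LAST_PLUS_FIRST6, (COHORT_ID, DOB), 64),
    _level(LAST_PLUS_FIRST6, (DOB,), 63),
    _level(NONE, (COHORT_ID, DOB, SSN_FULL), 62),
    _level(NONE, (DOB, SSN_FULL), 61),
    _level(LAST_ONLY, (DOB,), 59),
    _level(LAST_ONLY, (COHORT_ID,), 58),
    _level(NONE, (COHORT_ID, DOB, SSN_PARTIAL), 40),
    _level(NONE, (DOB, SSN_PARTIAL), 38),
    _level(NONE, (COHORT_ID, DOB), 30),
    _level(NONE, (COHORT_ID,), 20),
)

DEFAULT_THRESHOLD = 61


@dataclass(frozen=True)
class MatchAlgorithm:
    """An ordered scoring cascade plus the sharing threshold."""

    levels: tuple[MatchLevel, ...] = _DEFAULT_LEVELS
    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        scores: list[int] = []
        for level in self.levels:
            scores.append(level.score_person_view)
            if level.score_alias is not None:
                scores.append(level.score_alias)
        if len(scores) != len(set(scores)):
            raise ValueError("levels must not share scores")
        pv_scores = [lvl.score_person_view for lvl in self.levels]
        if pv_scores != sorted(pv_scores, reverse=True):
            raise ValueError("levels must be ordered by descending person-view score")

    @property
    def defined_scores(self) -> tuple[int, ...]:
        """All scores the cascade can emit, descending."""
        out: list[int] = []
        for level in self.levels:
            out.append(level.score_person_view)
            if level.score_alias is not None:
                out.append(level.score_alias)
        return tuple(sorted(out, reverse=True))

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "levels": [
                {
                    "name_rule": lvl.name_rule,
                    "required": sorted(lvl.required_vars),
                    "score_pv": lvl.score_person_view,
                    "score_alias": lvl.score_alias,
                }
                for lvl in self.levels
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MatchAlgorithm":
        payload = json.loads(text)
        levels = tuple(
            MatchLevel(
                name_rule=item["name_rule"],
                required_vars=frozenset(item["required"]),
                score_person_view=item["score_pv"],
                score_alias=item.get("score_alias"),
            )
            for item in payload["levels"]
        )
        return cls(levels=levels, threshold=payload["threshold"])


def default_algorithm() -> MatchAlgorithm:
    """The shipped cascade (28 levels, threshold 61)."""
    return MatchAlgorithm()


@dataclass(frozen=True)
class MatchResult:
    cohort_id: str
    person_id: str
    score: int
    level_description: str
    name_source: str  # person_view | alias | none
    shared: bool
    tie_flag: bool = False


# ---------------------------------------------------------------------------
# Pair scoring
# ---------------------------------------------------------------------------


def _last4(ssn: Optional[str]) -> Optional[str]:
    return ssn[-4:] if ssn else None


def _pair_facts(rec, surv) -> dict:
    """Evaluate every atomic criterion once for a pair."""
    facts = {
        COHORT_ID: (
            surv.prior_cohort_id is not None and surv.prior_cohort_id == rec.cohort_id
        ),
        DOB: rec.dob is not None and rec.dob == surv.dob,
        SSN_FULL: (
            rec.ssn is not None
            and surv.ssn is not None
            and len(rec.ssn) == 9
            and len(surv.ssn) == 9
            and rec.ssn == surv.ssn
        ),
        SSN_PARTIAL: (
            rec.ssn is not None
            and surv.ssn is not None
            and _last4(rec.ssn) == _last4(surv.ssn)
        ),
        BIRTH_SEX: (
            rec.birth_sex in ("M", "F") and rec.birth_sex == surv.birth_sex
        ),
    }

    first = normalize_name(rec.first_name)
    last = normalize_name(rec.last_name)
    pv_first = normalize_name(surv.first_name)
    pv_last = normalize_name(surv.last_name)

    facts["name_pv_full"] = (
        first is not None and last is not None
        and first == pv_first and last == pv_last
    )
    facts["name_alias_full"] = any(
        first is not None and last is not None
        and first == normalize_name(a_first) and last == normalize_name(a_last)
        for a_first, a_last in getattr(surv, "aliases", ())
    )
    facts["name_pv_last"] = last is not None and last == pv_last
    facts["name_pv_last_first6"] = (
        facts["name_pv_last"]
        and first is not None and pv_first is not None
        and first[:6] == pv_first[:6]
    )
    return facts


def _satisfies(level: MatchLevel, facts: dict) -> Optional[str]:
    """Name source ('person_view'/'alias'/'none') if the level is met, else None."""
    if not all(facts[var] for var in level.required_vars):
        return None
    if level.name_rule == NONE:
        return "none"
    if level.name_rule == LAST_ONLY:
        return "person_view" if facts["name_pv_last"] else None
    if level.name_rule == LAST_PLUS_FIRST6:
        return "person_view" if facts["name_pv_last_first6"] else None
    # FULL_NAME: person view checked first and wins at equal level
    if facts["name_pv_full"]:
        return "person_view"
    if level.score_alias is not None and facts["name_alias_full"]:
        return "alias"
    return None


def score_pair(rec, surv, alg: Optional[MatchAlgorithm] = None):
    """Score one cohort-side record against one surveillance record.

    ``rec`` is any object exposing ``cohort_id``, ``first_name``,
    ``last_name``, ``dob``, ``ssn`` and ``birth_sex`` (a SiteRecord or a
    merged eligible record).  Returns ``(score, level_description,
    name_source)`` for the highest-scoring satisfied level, or ``None``
    if no level is satisfied.
    """
    alg = alg or default_algorithm()
    facts = _pair_facts(rec, surv)
    # No level is satisfiable without at least one keyed agreement.
    if not (facts[COHORT_ID] or facts[DOB] or facts[SSN_PARTIAL] or facts[SSN_FULL]):
        return None
    best: Optional[tuple[int, str, str]] = None
    for level in alg.levels:
        source = _satisfies(level, facts)
        if source is None:
            continue
        score = (
            level.score_alias
            if source == "alias" and level.score_alias is not None
            else level.score_person_view
        )
        if best is None or score > best[0]:
            best = (score, level.description, source)
    return best


# ---------------------------------------------------------------------------
# Blocking and best-match selection
# ---------------------------------------------------------------------------


def generate_candidates(cohort_records: Sequence, surveillance_records: Sequence):
    """Candidate pairs sharing at least one blocking key.

    Blocking keys are Cohort ID (against the registry's prior Cohort ID),
    exact DOB, and the last 4 SSN digits.  Every level of the cascade
    requires at least one of those variables, so the candidate set is a
    superset of all scorable pairs.

    Returns a list of ``(cohort_index, surveillance_index)`` pairs in
    deterministic order.
    """
    by_cohort_id: dict = {}
    by_dob: dict = {}
    by_last4: dict = {}
    for i, rec in enumerate(cohort_records):
        by_cohort_id.setdefault(rec.cohort_id, []).append(i)
        if rec.dob is not None:
            by_dob.setdefault(rec.dob, []).append(i)
        if rec.ssn:
            by_last4.setdefault(_last4(rec.ssn), []).append(i)

    pairs: set[tuple[int, int]] = set()
    for j, surv in enumerate(surveillance_records):
        if surv.prior_cohort_id is not None:
            for i in by_cohort_id.get(surv.prior_cohort_id, ()):
                pairs.add((i, j))
        if surv.dob is not None:
            for i in by_dob.get(surv.dob, ()):
                pairs.add((i, j))
        if surv.ssn:
            for i in by_last4.get(_last4(surv.ssn), ()):
                pairs.add((i, j))
    return sorted(pairs)


def run_match(
    cohort_records: Sequence,
    surveillance_records: Sequence,
    alg: Optional[MatchAlgorithm] = None,
    *,
    exhaustive: bool = False,
) -> list[MatchResult]:
    """Match each cohort record to its best-scoring surveillance person.

    At most one result per cohort_id: the highest-scoring person wins, ties
    broken by lexicographically smallest person_id with ``tie_flag=True``.
    Several cohort_ids may map to the same person (multi-site enrollment).
    Output is sorted by cohort_id.  ``exhaustive=True`` scores the full
    cross product instead of blocked candidates (oracle mode for testing).
    """
    alg = alg or default_algorithm()
    if exhaustive:
        pairs: Iterable[tuple[int, int]] = (
            (i, j)
            for i in range(len(cohort_records))
            for j in range(len(surveillance_records))
        )
    else:
        pairs = generate_candidates(cohort_records, surveillance_records)

    # best[i] = (score, person_id, level, source, tie)
    best: dict[int, tuple] = {}
    for i, j in pairs:
        scored = score_pair(cohort_records[i], surveillance_records[j], alg)
        if scored is None:
            continue
        score, level, source = scored
        person_id = surveillance_records[j].person_id
        cur = best.get(i)
        if cur is None or score > cur[0]:
            best[i] = (score, person_id, level, source, False)
        elif score == cur[0] and person_id != cur[1]:
            winner = min(person_id, cur[1])
            if winner == person_id:
                best[i] = (score, person_id, level, source, True)
            else:
                best[i] = (cur[0], cur[1], cur[2], cur[3], True)

    results = [
        MatchResult(
            cohort_id=cohort_records[i].cohort_id,
            person_id=person_id,
            score=score,
            level_description=level,
            name_source=source,
            shared=score >= alg.threshold,
            tie_flag=tie,
        )
        for i, (score, person_id, level, source, tie) in best.items()
    ]
    results.sort(key=lambda r: r.cohort_id)
    return results
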