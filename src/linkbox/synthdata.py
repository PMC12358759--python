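"""Seeded generator of linked site/central/surveillance feeds with ground truth.

The generator emulates the error phenomena a deterministic matcher must
tolerate in registry data: misspelled names in the person view, reversed
name order captured as alias entries, extra alias variants, date-of-birth
typos, and Social Security numbers that are missing or recorded as the last
4 digits only.  Each simulated person carries one identity; enrollment at
one or more clinic sites yields one Cohort ID per enrollment, and a
configurable fraction of persons also exist in the surveillance registry
(persons not covered have no registry row at all and can never match).
Every corruption applied is logged in the ground truth's provenance list,
and the true cohort-to-person mapping is returned alongside the feeds.

All randomness flows through a single numpy Generator seeded from the
config; identical (config, seed) produce byte-identical output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from decimal import Decimal
from pathlib import Path
from typing import Optional

import numpy as np

from . import _names
from .records import (
    CentralRecord,
    DemographicProfile,
    LabRecord,
    SiteRecord,
    SurveillanceRecord,
    write_table,
)

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedFeeds", "ConfigError",
           "simulate", "corrupt_name", "write_feeds", "read_ground_truth"]


class ConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible."""


@dataclass
class SimulationConfig:
    """Generator parameters.

    Defaults describe a desk-scale cohort-registry linkage: 14 clinic
    sites, 93% registry coverage, about 5.3% of persons enrolled at two
    sites and 0.2% at three, with mild identifier corruption.
    """

    n_persons: int = 2000
    n_sites: int = 14
    surveillance_coverage: float = 0.93
    multi_enroll_2: float = 0.053
    multi_enroll_3: float = 0.002
    p_name_typo: float = 0.05
    p_name_reversed_alias: float = 0.05
    p_alias_extra: float = 0.3
    p_ssn_missing: float = 0.05
    p_ssn_partial_only: float = 0.03
    p_dob_typo: float = 0.02
    p_prior_cohort_id: float = 0.8
    labs_per_person: float = 6.0
    p_lab_shared: float = 0.6
    p_demog_discrepant: float = 0.05
    p_death: float = 0.08
    seed: int = 0
    # registry persons never enrolled in the cohort; None -> n_persons // 4
    n_background_persons: Optional[int] = None

    def validate(self) -> None:
        probs = {
            name: getattr(self, name)
            for name in (
                "surveillance_coverage", "multi_enroll_2", "multi_enroll_3",
                "p_name_typo", "p_name_reversed_alias", "p_alias_extra",
                "p_ssn_missing", "p_ssn_partial_only", "p_dob_typo",
                "p_prior_cohort_id", "p_lab_shared", "p_demog_discrepant",
                "p_death",
            )
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.multi_enroll_2 + self.multi_enroll_3 > 1:
            raise ConfigError("multi_enroll_2 + multi_enroll_3 must not exceed 1")
        if self.n_persons < 1:
            raise ConfigError("n_persons must be positive")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be positive")
        if self.n_sites < 3 and self.multi_enroll_3 > 0:
            raise ConfigError("multi_enroll_3 > 0 requires at least 3 sites")
        if self.n_sites < 2 and self.multi_enroll_2 > 0:
            raise ConfigError("multi_enroll_2 > 0 requires at least 2 sites")
        if self.p_ssn_missing + self.p_ssn_partial_only > 1:
            raise ConfigError("p_ssn_missing + p_ssn_partial_only must not exceed 1")
        if self.labs_per_person < 0:
            raise ConfigError("labs_per_person must be non-negative")


@dataclass
class GroundTruth:
    """True labels behind one simulated dataset.

    ``true_pairs`` maps every cohort_id to its registry person_id, or None
    for participants absent from the registry.  ``person_partition`` is the
    inverse restricted to covered persons.  ``true_new_labs`` counts, per
    cohort_id, the post-consent labs present on only one side; the per-ID
    counts are exact for singly-enrolled participants (for multi-enrolled
    persons the per-comparison view pools the person's labs).
    ``provenance`` logs every corruption applied as (entity id, phenomenon).
    """

    true_pairs: dict[str, Optional[str]] = field(default_factory=dict)
    person_partition: dict[str, list[str]] = field(default_factory=dict)
    true_new_labs: dict[str, dict[str, int]] = field(default_factory=dict)
    provenance: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SimulatedFeeds:
    site_records: list[SiteRecord]
    central_records: list[CentralRecord]
    surveillance_records: list[SurveillanceRecord]
    ground_truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Corruption primitives
# ---------------------------------------------------------------------------

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def corrupt_name(name: str, mode: str, rng: np.random.Generator) -> str:
    """Apply exactly one edit to a name: ``typo_swap`` (swap adjacent
    characters), ``typo_sub`` (substitute one character), or ``truncate``
    (drop the final character).  The result always differs from the input;
    modes that cannot change the input fall back to substitution.
    """
    if not name:
        raise ValueError("cannot corrupt an empty name")
    if mode not in ("typo_swap", "typo_sub", "truncate"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    if mode == "truncate" and len(name) > 1:
        return name[:-1]
    if mode == "typo_swap":
        swappable = [i for i in range(len(name) - 1) if name[i] != name[i + 1]]
        if swappable:
            pos = swappable[int(rng.integers(0, len(swappable)))]
            return name[:pos] + name[pos + 1] + name[pos] + name[pos + 2:]
        # single character or all-equal adjacent pairs: substitution instead
    pos = int(rng.integers(0, len(name)))
    choices = _ALPHABET.replace(name[pos].upper(), "") or "X"
    char = choices[int(rng.integers(0, len(choices)))]
    return name[:pos] + char + name[pos + 1:]


def _random_typo(name: str, rng: np.random.Generator) -> str:
    mode = ("typo_swap", "typo_sub", "truncate")[int(rng.integers(0, 3))]
    return corrupt_name(name, mode, rng)


def _perturb_dob(dob: date, rng: np.random.Generator) -> date:
    offsets = [d for d in range(-9, 10) if d != 0]
    shifted = dob + timedelta(days=int(offsets[int(rng.integers(0, len(offsets)))]))
    return min(shifted, date.today() - timedelta(days=1))


def _pick(rng: np.random.Generator, pool):
    return pool[int(rng.integers(0, len(pool)))]


def _random_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, max(span, 1))))


# ---------------------------------------------------------------------------
# Identity and payload builders
# ---------------------------------------------------------------------------


@dataclass
class _Identity:
    first: str
    last: str
    dob: date
    ssn: str
    birth_sex: str
    demographics: DemographicProfile


def _make_identity(rng: np.random.Generator) -> _Identity:
    first = _pick(rng, _names.FIRST_NAMES)
    last = _pick(rng, _names.LAST_NAMES)
    dob = _random_date(rng, date(1940, 1, 1), date(2000, 12, 31))
    # leading 9: never a validly issued number
    ssn = "9" + "".join(str(int(d)) for d in rng.integers(0, 10, size=8))
    birth_sex = "M" if rng.random() < 0.6 else "F"
    hiv_dx = _random_date(rng, dob + timedelta(days=18 * 365), date(2022, 9, 30))
    aids_dx = (
        _random_date(rng, hiv_dx, date(2022, 9, 30)) if rng.random() < 0.25 else None
    )
    demog = DemographicProfile(
        vital_status="alive",
        gender=birth_sex,
        sex_at_birth=birth_sex,
        race=_pick(rng, _names.RACES),
        hiv_transmission_risk=_pick(rng, _names.TRANSMISSION_RISKS),
        state_of_residence="DC" if rng.random() < 0.85 else _pick(rng, _names.STATES),
        hiv_diagnosis_date=hiv_dx,
        aids_diagnosis_date=aids_dx,
    )
    return _Identity(first, last, dob, ssn, birth_sex, demog)


def _make_lab(rng: np.random.Generator, after: date, facility: Optional[str]) -> LabRecord:
    sample = _random_date(rng, after + timedelta(days=1), after + timedelta(days=3000))
    kind = ("CD4_count", "CD4_percent", "viral_load")[int(rng.integers(0, 3))]
    if kind == "CD4_count":
        result, interp = Decimal(int(rng.integers(10, 1500))), "EQ"
    elif kind == "CD4_percent":
        result, interp = Decimal(int(rng.integers(1, 60))), "EQ"
    else:
        if rng.random() < 0.5:
            result, interp = Decimal(20), "UNDETECTABLE"
        else:
            result, interp = Decimal(int(rng.integers(40, 500000))), "EQ"
    return LabRecord(sample, kind, result, interp, facility)


def _perturb_demographics(
    demog: DemographicProfile, p: float, rng: np.random.Generator,
    log, entity: str,
) -> DemographicProfile:
    changes = {}
    pools = {
        "race": _names.RACES,
        "hiv_transmission_risk": _names.TRANSMISSION_RISKS,
        "state_of_residence": _names.STATES,
        "gender": ["M", "F"],
    }
    for fld in ("race", "hiv_transmission_risk", "state_of_residence", "gender",
                "hiv_diagnosis_date"):
        if rng.random() >= p:
            continue
        if rng.random() < 0.5:
            changes[fld] = None  # recorded as missing on this side
        elif fld == "hiv_diagnosis_date":
            current = getattr(demog, fld)
            if current is not None:
                changes[fld] = _perturb_dob(current, rng)
        else:
            pool = [v for v in pools[fld] if v != getattr(demog, fld)]
            changes[fld] = _pick(rng, pool)
        log.append((entity, f"demographic_discrepancy:{fld}"))
    return replace(demog, **changes) if changes else demog


# ---------------------------------------------------------------------------
# The generator
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimulatedFeeds:
    """Generate the three linked feeds plus ground truth for one config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    log = truth.provenance

    site_records: list[SiteRecord] = []
    central_records: list[CentralRecord] = []
    surveillance_records: list[SurveillanceRecord] = []

    cohort_counter = 0
    for p_idx in range(config.n_persons):
        person = _make_identity(rng)
        person_id = f"P{p_idx:06d}"
        covered = rng.random() < config.surveillance_coverage

        draw = rng.random()
        if draw < config.multi_enroll_3:
            n_enroll = 3
        elif draw < config.multi_enroll_3 + config.multi_enroll_2:
            n_enroll = 2
        else:
            n_enroll = 1
        sites = rng.choice(config.n_sites, size=n_enroll, replace=False)

        cohort_ids: list[str] = []
        consents: list[date] = []
        shared_labs_all: list[LabRecord] = []
        surv_only_labs: list[LabRecord] = []

        for enroll_idx in range(n_enroll):
            cohort_id = f"C{cohort_counter:06d}"
            cohort_counter += 1
            cohort_ids.append(cohort_id)
            site_id = f"S{int(sites[enroll_idx]) + 1:02d}"

            ssn: Optional[str] = person.ssn
            roll = rng.random()
            if roll < config.p_ssn_missing:
                ssn = None
                log.append((cohort_id, "ssn_missing"))
            elif roll < config.p_ssn_missing + config.p_ssn_partial_only:
                ssn = person.ssn[-4:]
                log.append((cohort_id, "ssn_partial_only"))

            site_records.append(
                SiteRecord(
                    cohort_id=cohort_id,
                    site_id=site_id,
                    first_name=person.first.title(),
                    last_name=person.last.title(),
                    dob=person.dob,
                    ssn=ssn,
                    birth_sex=person.birth_sex,
                )
            )

            consent = _random_date(rng, date(2011, 1, 1), date(2022, 9, 30))
            consents.append(consent)
            n_labs = int(rng.poisson(config.labs_per_person))
            cohort_labs: list[LabRecord] = []
            n_new_to_cohort = 0
            n_shared_this = 0
            for _ in range(n_labs):
                lab = _make_lab(rng, consent, facility=None)
                share_roll = rng.random()
                if share_roll < config.p_lab_shared:
                    cohort_labs.append(lab)
                    shared_labs_all.append(
                        replace(lab, facility=_pick(rng, _names.FACILITIES))
                    )
                    n_shared_this += 1
                elif share_roll < config.p_lab_shared + (1 - config.p_lab_shared) / 2:
                    cohort_labs.append(lab)  # cohort-only
                else:
                    surv_only_labs.append(
                        replace(lab, facility=_pick(rng, _names.FACILITIES))
                    )
                    n_new_to_cohort += 1

            treatments = tuple(
                (
                    _pick(rng, _names.ARV_DRUGS),
                    _random_date(rng, consent, date(2022, 9, 30)),
                    None,
                )
                for _ in range(int(rng.integers(1, 4)))
            )

            central_records.append(
                CentralRecord(
                    cohort_id=cohort_id,
                    consent_date=consent,
                    demographics=person.demographics,
                    labs=tuple(
                        sorted(cohort_labs, key=lambda l: (l.sample_date, l.lab_type))
                    ),
                    treatments=treatments,
                )
            )
            truth.true_new_labs[cohort_id] = {
                "new_to_cohort": n_new_to_cohort,
                "new_to_surveillance": len(cohort_labs) - n_shared_this,
            } if covered else {"new_to_cohort": 0, "new_to_surveillance": 0}
            truth.true_pairs[cohort_id] = person_id if covered else None

        if not covered:
            continue

        truth.person_partition[person_id] = list(cohort_ids)

        # person-view name, possibly misspelled; aliases may rescue it
        pv_first, pv_last = person.first, person.last
        aliases: list[tuple[Optional[str], Optional[str]]] = []
        if rng.random() < config.p_name_typo:
            if rng.random() < 0.5:
                pv_first = _random_typo(pv_first, rng)
                log.append((person_id, "name_typo:first"))
            else:
                pv_last = _random_typo(pv_last, rng)
                log.append((person_id, "name_typo:last"))
            if rng.random() < 0.5:
                aliases.append((person.first, person.last))  # document variant
        if rng.random() < config.p_name_reversed_alias:
            aliases.append((person.last, person.first))
            log.append((person_id, "reversed_name_alias"))
        n_extra = 0
        while n_extra < 3 and rng.random() < config.p_alias_extra:
            aliases.append((_random_typo(person.first, rng), person.last))
            n_extra += 1

        dob = person.dob
        if rng.random() < config.p_dob_typo:
            dob = _perturb_dob(dob, rng)
            log.append((person_id, "dob_typo"))

        prior = cohort_ids[0] if rng.random() < config.p_prior_cohort_id else None

        deceased = rng.random() < config.p_death
        demog = _perturb_demographics(
            person.demographics, config.p_demog_discrepant, rng, log, person_id
        )
        if deceased:
            demog = replace(demog, vital_status="deceased")

        ois = tuple(
            (_pick(rng, _names.OI_CONDITIONS),
             _random_date(rng, date(2011, 1, 1), date(2024, 6, 30)))
            for _ in range(int(rng.integers(1, 4)))
        ) if rng.random() < 0.15 else ()

        # a few pre-consent labs exercise the consent-date exclusion; dated
        # on/before the earliest consent so the comparison always drops them
        pre_labs = tuple(
            replace(
                _make_lab(rng, date(2005, 1, 1), _pick(rng, _names.FACILITIES)),
                sample_date=_random_date(rng, date(2005, 1, 1), min(consents)),
            )
            for _ in range(int(rng.poisson(0.3)))
        )
        surv_labs = tuple(
            sorted(
                shared_labs_all + surv_only_labs + list(pre_labs),
                key=lambda l: (l.sample_date, l.lab_type, str(l.result)),
            )
        )

        surveillance_records.append(
            SurveillanceRecord(
                person_id=person_id,
                first_name=pv_first.title(),
                last_name=pv_last.title(),
                aliases=tuple(aliases),
                dob=dob,
                ssn=person.ssn,
                birth_sex=person.birth_sex,
                prior_cohort_id=prior,
                demographics=demog,
                labs=surv_labs,
                opportunistic_infections=ois,
                vital_status="deceased" if deceased else "alive",
                death_date=_random_date(rng, date(2012, 1, 1), date(2024, 6, 30))
                if deceased else None,
                cause_of_death=_pick(rng, _names.CAUSES_OF_DEATH) if deceased else None,
            )
        )

    n_background = (
        config.n_background_persons
        if config.n_background_persons is not None
        else config.n_persons // 4
    )
    for b_idx in range(n_background):
        person = _make_identity(rng)
        person_id = f"B{b_idx:06d}"
        labs = tuple(
            _make_lab(rng, date(2011, 1, 1), _pick(rng, _names.FACILITIES))
            for _ in range(int(rng.poisson(2.0)))
        )
        surveillance_records.append(
            SurveillanceRecord(
                person_id=person_id,
                first_name=person.first.title(),
                last_name=person.last.title(),
                dob=person.dob,
                ssn=person.ssn,
                birth_sex=person.birth_sex,
                demographics=person.demographics,
                labs=labs,
                vital_status="alive",
            )
        )

    surveillance_records.sort(key=lambda r: r.person_id)
    return SimulatedFeeds(
        site_records=site_records,
        central_records=central_records,
        surveillance_records=surveillance_records,
        ground_truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_feeds(feeds: SimulatedFeeds, out_dir) -> dict[str, Path]:
    """Write sites.csv, central.csv, surveillance.csv and ground_truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "site": out / "sites.csv",
        "central": out / "central.csv",
        "surveillance": out / "surveillance.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_table(feeds.site_records, paths["site"], "site")
    write_table(feeds.central_records, paths["central"], "central")
    write_table(feeds.surveillance_records, paths["surveillance"], "surveillance")
    with open(paths["ground_truth"], "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["cohort_id", "person_id"])
        for cohort_id in sorted(feeds.ground_truth.true_pairs):
            person_id = feeds.ground_truth.true_pairs[cohort_id]
            writer.writerow([cohort_id, person_id or ""])
    return paths


def read_ground_truth(path) -> GroundTruth:
    """Read a ground_truth.csv back into a GroundTruth (pairs + partition)."""
    truth = GroundTruth()
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            person_id = row["person_id"] or None
            truth.true_pairs[row["cohort_id"]] = person_id
            if person_id:
                truth.person_partition.setdefault(person_id, []).append(row["cohort_id"])
    return truth
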