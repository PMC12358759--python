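# Methods

## The linkage model

`linkbox` implements a deterministic, cascade-based record linkage between
two parties: a clinical cohort (site files with identifiers plus a
deidentified central file keyed by Cohort ID) and an HIV surveillance
registry (a person-view file with alias names). The pipeline is

1. **verify** — each input file is checked against its schema template;
   every issue is reported as (row, field, message), deterministically
   ordered. A run aborts on any issue unless forced.
2. **filter** — Cohort IDs are intersected between the central and site
   feeds. IDs in only one feed are excluded and written to two filter
   reports; the intersection proceeds to matching. A Cohort ID enrolled at
   several sites enters once (first-seen site row supplies the identifiers;
   cross-site identifier disagreements are reported, first-seen wins).
3. **match** — every eligible record is scored against candidate registry
   persons; the highest-scoring person wins, ties broken by smallest
   person ID with a tie flag. At most one result per Cohort ID; several
   Cohort IDs may map to one person.
4. **dedup** — shared results (score ≥ threshold) are clustered by person to
   count unique persons and multi-site enrollment. Sub-threshold matches
   never merge persons.
5. **reports** — one CSV per report kind per recipient; cohort-recipient
   tables are checked column-wise against a deny-list (name, DOB, SSN,
   person ID) before writing.
6. **validate** (optional) — results are labeled against ground truth,
   precision is tabulated by score band, and a threshold is selected.

### Scoring semantics

For each pair the engine evaluates nine atomic facts once — Cohort ID
agreement (registry's prior Cohort ID vs. the record's), exact DOB equality,
full-SSN equality (both 9 digits), partial-SSN equality (last 4 digits),
birth-sex equality (unknown never agrees), and four name facts (person-view
full name, alias full name, person-view last name, person-view last name +
first 6 letters of the first name) — then takes the highest-scoring
satisfied level. Conventions:

- Names compare by exact equality of normalized tokens (upper-case;
  whitespace, hyphens, apostrophes, periods removed). Empty/all-punctuation
  normalizes to missing. No edit-distance or phonetic matching: the paperless
  tolerance mechanism is the cascade itself plus registry alias names.
- A full-name alias match must agree with a single alias entry on both
  first and last; the person view is checked first and wins at equal level
  (its score is one point higher by construction).
- "First 6 letters" compares the first `min(6, length)` characters of the
  normalized first names plus full last-name equality, person view only.
- Last-name-only and first-6 levels use the person view only; aliases count
  only for full-name levels.
- A 9-digit SSN satisfies both full and partial criteria (last-4 equality is
  implied), so the full-SSN level dominates through highest-level-wins; a
  4-digit stored SSN can satisfy partial criteria only.
- DOB is exact date equality — DOB typos are a data phenomenon the cascade
  tolerates through other levels, not a comparison feature.
- Any criterion over a field missing on either side is unsatisfied; missing
  data yields a lower level or no match, never an error.
- Reversed name order is handled through alias entries (the generator emits
  a swapped-order alias), not a built-in swap rule.

### Blocking

Candidate pairs share at least one key among {Cohort ID ↔ prior Cohort ID,
exact DOB, SSN last-4}. Every cascade level requires at least one of those
variables (asserted by a test over the shipped table), so blocking is
provably lossless; a dedicated suite checks blocked output equals the
exhaustive cross product pair-for-pair on ~200×200 inputs over 20 seeds.

### Threshold selection

`select_threshold` returns the smallest defined score whose cumulative
precision at-or-above meets the target (default 0.99), scanning defined
scores upward; if none qualifies it returns the maximum score with a
warning flag. Uncertain labels are excluded from precision denominators by
default; `uncertain_as_false=True` reproduces the stricter review
convention that counts unresolved pairs as false. Ground-truth labels are
never uncertain.

## The synthetic-data generator

The generator is first-class, tested code: it emulates the registry error
phenomena the matcher must tolerate and returns ground truth for
validation. Each person has one identity (name from packaged pools, DOB
1940–2000, synthetic 9-digit SSN always starting with 9 so it can never
resemble an issued number, birth sex, demographics). Defaults describe the
study conditions: 14 sites, registry coverage 0.93, two-site enrollment
probability 0.053 and three-site 0.002 (the multi-enrollment fractions
implied by a ~8.6k-person deduplicated cohort with 453 two-site and 17
three-site persons), plus mild corruption:

| parameter | default | meaning |
|---|---|---|
| `p_name_typo` | 0.05 | person-view first *or* last name gets one edit (swap/substitute/truncate); with prob. 0.5 an alias preserves the true name (document variants) |
| `p_name_reversed_alias` | 0.05 | alias with first/last swapped |
| `p_alias_extra` | 0.3 | geometric count (cap 3) of extra typo aliases |
| `p_ssn_missing` | 0.05 | site feed lacks the SSN |
| `p_ssn_partial_only` | 0.03 | site feed stores last 4 digits only |
| `p_dob_typo` | 0.02 | registry DOB shifted by 1–9 days |
| `p_prior_cohort_id` | 0.8 | registry carries a prior-linkage Cohort ID (first enrollment only) |
| `labs_per_person` | 6.0 | Poisson mean labs per enrollment |
| `p_lab_shared` | 0.6 | lab appears on both sides; remainder split evenly cohort-only / registry-only |
| `p_demog_discrepant` | 0.05 | per-field registry demographic perturbed or blanked |
| `p_death` | 0.08 | registry records a death the cohort missed |

SSN corruption applies to the site feed (clinics lose or truncate SSNs),
name and DOB corruption to the registry person view (transcription across
source documents); the placement is a modelling choice — the matcher only
sees the disagreement. Registry "background" persons never enrolled in the
cohort (default `n_persons // 4`) make the registry a superset of the
cohort. Persons outside coverage have no registry row at all. A small
Poisson number of registry labs is dated before the earliest consent to
exercise the consent-date exclusion. All randomness flows through one
seeded numpy Generator; identical config ⇒ byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic name/DOB collision density (real
registries produce many more near-matches, hence real false-match rates and
threshold pressure are higher; on synthetic data false matches above the
floor levels are rare and the selected threshold typically relaxes to the
cascade minimum), nicknames and hyphenation variants beyond single edits,
shared-household SSN errors, geography and care-seeking behaviour, and
within-person demographic drift over time.

With coverage 0.93 and the mild defaults, a covered true pair fails to
reach the threshold only when several corruptions coincide (roughly
`P(name unusable) × P(DOB or SSN unusable)` ≈ 0.2%), so the shared-match
fraction recovers the configured coverage; the suite asserts recovery
within 3 standard errors over 10 seeds at 2,000 persons. With DOB and SSN
corruption disabled every covered true pair reaches the DOB+SSN floor level
(61) regardless of name noise; this is asserted directly.

## Report suite and redaction

Two recipients: `health_dept` (authorized for identifiers) and `cohort`
(never sees name, DOB, SSN, or person ID — its match report is Cohort ID +
score only). The treatment report is health-department-only; requesting it
for the cohort raises a redaction error. Redaction is enforced structurally
(deny-listed columns) and verified empirically: a test plants known
identifiers via the generator and greps every cohort-recipient file for
person IDs, SSNs, DOBs and names as whole words.

Lab comparison: labs dated on or before the consent date are excluded
entirely ("must occur after" read strictly). Remaining labs pair greedily
within each (sample date, lab type) group in result-sorted order —
a deterministic convention; the source workflow does not specify pairing —
and each pair is coded `DUPLICATE` (result and interpretation agree),
`RESULT_INTERP_DIFF`, or `RESULT_DIFF`; unpaired labs are `NEW` to the side
lacking them. Result equality is exact after trimming trailing zeros
(200.0 ≡ 200); recording-convention differences are expressed by the codes,
not by a numeric tolerance. Conservation holds by construction:
|side's post-consent labs| = |coded pairs| + |that side's unpaired labs|.

Demographics comparison emits one row per field that is missing or unequal
after canonicalization (case/whitespace-insensitive for strings, exact for
dates); fully concordant matches produce no row. The alternative convention
— an all-blank row for every matched Cohort ID — was considered and not
adopted; row presence encodes "something to reconcile".

Percentages in formatted summaries round half-up to one decimal
(`format_percent(9060, 9744) == "93.0"`).

## Numerical and design conventions

- Dates are ISO 8601 everywhere; any other dialect is a verification issue.
- Missing is the empty cell on disk and `None` in memory, never `""`.
- SSNs are stored digits-only; hyphens stripped on read; lengths other than
  9 or 4 become missing with a warning.
- File keys: site rows key on (Cohort ID, site ID) — one row per enrollment;
  central on Cohort ID; surveillance on person ID. Duplicates raise a
  key-collision error naming the offending keys.
- Ties in best-match selection break to the lexicographically smallest
  person ID and set `tie_flag`; the cascade's distinct-score invariant makes
  within-person ties impossible.
- The algorithm table and threshold are config-editable JSON but ship
  frozen; a threshold override must be one of the cascade's defined scores.
- Middle names are not used: only first/last names appear in the cascade.
- The pipeline materializes stage outputs to disk (auditability over speed
  at desk scale); reruns on identical inputs are byte-identical except
  stage timings in the manifest.

## Problem sizes used in the test suite

Unit tests run on constructed pairs and feeds of 50–400 persons. The
blocking-equivalence suite uses 200 persons (+15 background) over 20 seeds;
parameter recovery uses 2,000 persons over 10 seeds; worked-example
arithmetic uses the printed counts directly (10,086/9,961 filter inputs,
9,060 shared matches, 9,378 labeled pairs). The full suite completes in
well under a minute on one CPU.

## Known limitations

- Registry-side duplicate persons are not resolved: each cohort record
  keeps one best match (ties flagged), and no transitive entity resolution
  is attempted beyond the cohort→person mapping.
- The four lab-group codes are this package's minimal scheme spanning
  "which variables matched"; deployments may need finer codes.
- Synthetic false-match rates are far below real-world rates (see
  generator non-goals), so threshold selection on synthetic data
  demonstrates the mechanism, not an operating point.
- No probabilistic (Fellegi–Sunter) scoring, no clerical-review workflow,
  and no cryptographic/hosting layer: this is the analytic core of the
  workflow, not the secure enclave around it.
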