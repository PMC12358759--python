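# linkbox

**Deterministic record linkage between a clinical HIV cohort and a
health-department surveillance registry, at desk scale.**

Longitudinal HIV cohorts routinely link their participant rosters to public
health surveillance registries: the linkage fills in missing laboratory
results (CD4 counts, viral loads), surfaces unreported deaths, and reveals
participants enrolled at more than one clinic site. Because the two parties
hold different identifiers and different authorizations — the health
department may see protected health information, the study team may not —
the linkage must be deterministic, auditable, and strictly redacted per
recipient.

`linkbox` is an open toolkit for that workflow. It provides:

- **records** — typed readers/writers and template verification for the three
  CSV feeds: clinic *site* files (Cohort ID + name, DOB, SSN, birth sex), the
  deidentified *central* cohort file (demographics, consent date, labs,
  treatments), and the *surveillance* person-view file (alias names, labs
  with facility, opportunistic infections, vital status).
- **filter_stage** — Cohort-ID reconciliation between central and site
  feeds; only IDs present in both proceed to matching, the rest go to two
  filter reports.
- **match_engine** — the deterministic multi-level scoring cascade (below),
  candidate blocking, and best-match selection with a sharing threshold.
- **dedup** — clustering of shared matches by registry person to enumerate
  unique persons and multi-site enrollment.
- **compare_reports** — the recipient-redacted report suite: match/unmatched
  reports, demographics discrepancies, lab comparison with lab-group coding,
  lab-site, opportunistic-infection and treatment reports.
- **synthdata** — a seeded generator of linked feeds with ground-truth pair
  labels and realistic identifier corruption (misspellings, reversed-order
  aliases, DOB typos, missing or partial SSNs).
- **validation** — labeling against ground truth, precision by score band,
  and threshold selection.
- **app / cli** — the `linkbox` command and the end-to-end pipeline
  (verify → filter → match → dedup → reports → validate) driven by a YAML
  project template, with a JSON run manifest.

## The matching cascade

Each record pair is scored at the highest level of an ordered cascade it
satisfies. A level combines a **name rule** — full first+last name, last
name only, last name plus the first 6 letters of the first name, or no name
requirement — with required non-name variables drawn from
{Cohort ID, DOB, full SSN, partial SSN (last 4 digits), birth sex}. Scores
run from 20 (Cohort ID only) to 100 (full name + Cohort ID + DOB + SSN +
birth sex). Full-name levels carry a twin score one point lower for a match
against a registry *alias* name rather than the person-view name (e.g.
100/99, 98/97, …). All comparisons are exact after normalization
(upper-case, punctuation and whitespace stripped; SSNs digits-only); there
is no phonetic or probabilistic fuzziness — tolerance comes from the
cascade and from alias names. Pairs scoring at or above the **sharing
threshold** (61 by default) are eligible for data exchange; sub-threshold
matches are still reported, flagged `shared=False`.

The shipped cascade has 28 levels (44 distinct scores) and is editable as
JSON for other deployments.

## Worked example

Generate a synthetic linkage project (2,000 persons, 14 sites, 93% registry
coverage, mild identifier corruption) and run the full pipeline:

```bash
linkbox simulate --seed 7 --out data
cat > project.yaml <<EOF
inputs:
  site: data/sites.csv
  central: data/central.csv
  surveillance: data/surveillance.csv
out_dir: out
truth: data/ground_truth.csv
EOF
linkbox run --template project.yaml
```

which prints the run counts:

```json
{
  "central_records": 2129,
  "site_records": 2129,
  "eligible": 2129,
  "central_only": 0,
  "site_only": 0,
  "identifier_conflicts": 0,
  "matched_any_score": 1983,
  "shared": 1977,
  "unique_persons": 1857,
  "multi_site_persons": 114,
  "cluster_size_histogram": {"1": 1743, "2": 108, "3": 6},
  "selected_threshold": 20,
  "threshold_warning": false
}
```

Reading the numbers: the 2,000 simulated persons yield 2,129 Cohort IDs
(multi-site enrollment); all are eligible because the simulated central and
site feeds agree. 1,977 of 2,129 (92.9%) match the registry at score ≥ 61,
recovering the configured 93% coverage; clustering the shared matches gives
1,857 unique persons of whom 114 are enrolled at more than one site. On this
synthetic run no false matches survive blocking, so validation finds perfect
precision in every band and the selected threshold relaxes to the cascade's
minimum score of 20 — real registry data, with far denser name/DOB
collisions, is what pushes the operating threshold up to 61.

Per-recipient reports land under `out/cohort/` and `out/health_dept/`; the
cohort copies contain no names, DOBs, SSNs or registry person IDs:

```
$ head -3 out/cohort/match.csv
cohort_id,score
C000000,100
C000001,100
```

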