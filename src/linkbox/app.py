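"""End-to-end pipeline orchestration and project templates.

A project template (YAML) is the analog of an administrator-editable
template: it binds the three input feeds (with optional column-name
mappings), names the matching-algorithm file and an optional threshold
override, lists the reports to generate per recipient, and sets the output
directory.  ``run_pipeline`` executes verify → reconcile → match → cluster →
reports (→ optional validation), materializing each stage to disk, and
returns a manifest recording input digests, per-report row counts and stage
timings.  Two runs on identical inputs produce identical report files;
only the timings differ.

Logging at INFO level reports counts only, never identifier values.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import compare_reports, dedup, records, validation
from .filter_stage import FilterOutcome, reconcile
from .match_engine import MatchAlgorithm, MatchResult, default_algorithm, run_match

__all__ = ["ProjectTemplate", "PipelineError", "run_pipeline"]

logger = logging.getLogger("linkbox")


class PipelineError(RuntimeError):
    """A stage failed: verification issues without --force, bad config, ..."""


_DEFAULT_REPORTS = [
    {"kind": kind, "recipient": recipient}
    for recipient in compare_reports.RECIPIENTS
    for kind in compare_reports.recipient_kinds(recipient)
]


@dataclass
class ProjectTemplate:
    site_files: list
    central_file: str
    surveillance_file: str
    out_dir: str
    algorithm_file: Optional[str] = None
    threshold_override: Optional[int] = None
    reports: list = field(default_factory=lambda: list(_DEFAULT_REPORTS))
    truth_file: Optional[str] = None
    target_precision: float = 0.99
    column_maps: dict = field(default_factory=dict)  # feed -> {raw: schema}
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ProjectTemplate":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        inputs = raw.get("inputs", {})
        sites = inputs.get("site", [])
        if isinstance(sites, str):
            sites = [sites]
        kwargs = dict(
            site_files=list(sites),
            central_file=inputs.get("central"),
            surveillance_file=inputs.get("surveillance"),
            out_dir=raw.get("out_dir", "out"),
            algorithm_file=raw.get("algorithm"),
            threshold_override=raw.get("threshold"),
            truth_file=raw.get("truth"),
            target_precision=raw.get("target_precision", 0.99),
            column_maps=raw.get("column_maps", {}),
            force=bool(raw.get("force", False)),
        )
        if "reports" in raw:
            kwargs["reports"] = raw["reports"]
        template = cls(**kwargs)
        template.validate()
        return template

    def validate(self) -> None:
        if not self.site_files:
            raise PipelineError("template names no site files")
        if not self.central_file or not self.surveillance_file:
            raise PipelineError("template must name central and surveillance files")
        for entry in self.reports:
            kind, recipient = entry["kind"], entry["recipient"]
            if kind not in compare_reports.REPORT_KINDS:
                raise PipelineError(f"unknown report kind {kind!r}")
            if recipient not in compare_reports.RECIPIENTS:
                raise PipelineError(f"unknown recipient {recipient!r}")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_algorithm(template: ProjectTemplate) -> MatchAlgorithm:
    if template.algorithm_file:
        path = Path(template.algorithm_file)
        if not path.exists():
            raise PipelineError(f"algorithm file not found: {path}")
        alg = MatchAlgorithm.from_json(path.read_text(encoding="utf-8"))
    else:
        alg = default_algorithm()
    if template.threshold_override is not None:
        if template.threshold_override not in alg.defined_scores:
            raise PipelineError(
                f"threshold override {template.threshold_override} is not a defined score"
            )
        alg = MatchAlgorithm(levels=alg.levels, threshold=template.threshold_override)
    return alg


def write_match_results(results: Sequence[MatchResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["cohort_id", "person_id", "score", "level", "name_source", "shared", "tie_flag"]
        )
        for r in results:
            writer.writerow(
                [r.cohort_id, r.person_id, r.score, r.level_description,
                 r.name_source, int(r.shared), int(r.tie_flag)]
            )


def read_match_results(path) -> list[MatchResult]:
    out = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            out.append(
                MatchResult(
                    cohort_id=row["cohort_id"],
                    person_id=row["person_id"],
                    score=int(row["score"]),
                    level_description=row["level"],
                    name_source=row["name_source"],
                    shared=bool(int(row["shared"])),
                    tie_flag=bool(int(row["tie_flag"])),
                )
            )
    return out


def _write_id_list(ids: Sequence[str], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["cohort_id"])
        for cid in ids:
            writer.writerow([cid])


def run_pipeline(template: ProjectTemplate) -> dict:
    """Execute the full linkage pipeline described by a project template.

    Returns (and writes to ``<out_dir>/manifest.json``) a manifest with
    input digests, the algorithm digest and threshold, per-stage timings,
    stage counts and one entry per emitted report with its row count.
    Raises :class:`PipelineError` if any input fails verification and the
    template does not set ``force``.
    """
    template.validate()
    out_dir = Path(template.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alg = load_algorithm(template)
    manifest: dict = {
        "inputs": {},
        "algorithm_sha256": hashlib.sha256(alg.to_json().encode()).hexdigest(),
        "threshold": alg.threshold,
        "stages": {},
        "counts": {},
        "reports": [],
    }
    timings = manifest["stages"]

    # --- verify -----------------------------------------------------------
    t0 = time.perf_counter()
    feeds = [(path, "site") for path in template.site_files]
    feeds += [(template.central_file, "central"), (template.surveillance_file, "surveillance")]
    for path, schema in feeds:
        if not Path(path).exists():
            raise PipelineError(f"input file not found: {path}")
        issues = records.verify_file(
            path, schema, column_map=template.column_maps.get(schema)
        )
        manifest["inputs"][str(path)] = _sha256(path)
        if issues and not template.force:
            first = issues[0]
            raise PipelineError(
                f"verification failed for {path} (row {first.row}, "
                f"field {first.field}): {first.issue}"
            )
        if issues:
            logger.warning("%s: %d verification issues (forced)", path, len(issues))
    timings["verify"] = time.perf_counter() - t0

    # --- read + reconcile -------------------------------------------------
    t0 = time.perf_counter()
    site_records = []
    for path in template.site_files:
        site_records.extend(
            records.read_table(
                path, "site", column_map=template.column_maps.get("site")
            ).records
        )
    central = records.read_table(
        template.central_file, "central", column_map=template.column_maps.get("central")
    ).records
    surveillance = records.read_table(
        template.surveillance_file,
        "surveillance",
        column_map=template.column_maps.get("surveillance"),
    ).records
    outcome: FilterOutcome = reconcile(central, site_records)
    stage_dir = out_dir / "stages"
    stage_dir.mkdir(exist_ok=True)
    _write_id_list(outcome.central_only_ids, stage_dir / "filter_central_only.csv")
    _write_id_list(outcome.site_only_ids, stage_dir / "filter_site_only.csv")
    timings["filter"] = time.perf_counter() - t0
    manifest["counts"].update(
        {
            "central_records": len(central),
            "site_records": len(site_records),
            "eligible": len(outcome.eligible),
            "central_only": len(outcome.central_only_ids),
            "site_only": len(outcome.site_only_ids),
            "identifier_conflicts": len(outcome.conflicts),
        }
    )
    logger.info(
        "filter: %d eligible, %d central-only, %d site-only",
        len(outcome.eligible), len(outcome.central_only_ids), len(outcome.site_only_ids),
    )

    # --- match ------------------------------------------------------------
    t0 = time.perf_counter()
    results = run_match(outcome.eligible, surveillance, alg)
    write_match_results(results, stage_dir / "match_results.csv")
    shared = [r for r in results if r.shared]
    timings["match"] = time.perf_counter() - t0
    manifest["counts"]["matched_any_score"] = len(results)
    manifest["counts"]["shared"] = len(shared)
    logger.info("match: %d results, %d at or above threshold %d",
                len(results), len(shared), alg.threshold)

    # --- dedup ------------------------------------------------------------
    t0 = time.perf_counter()
    site_map = {e.cohort_id: e.site_ids for e in outcome.eligible}
    clusters = dedup.cluster_by_person(shared, site_map)
    n_multi, histogram = dedup.multi_site_summary(clusters)
    timings["dedup"] = time.perf_counter() - t0
    manifest["counts"]["unique_persons"] = len(clusters)
    manifest["counts"]["multi_site_persons"] = n_multi
    manifest["counts"]["cluster_size_histogram"] = {
        str(k): v for k, v in histogram.items()
    }
    logger.info("dedup: %d unique persons, %d multi-site", len(clusters), n_multi)

    # --- reports ----------------------------------------------------------
    t0 = time.perf_counter()
    inputs = {
        "results": results,
        "eligible": outcome.eligible,
        "eligible_by_id": {e.cohort_id: e for e in outcome.eligible},
        "surveillance_by_id": {s.person_id: s for s in surveillance},
        "clusters": clusters,
        "filter_outcome": outcome,
    }
    for entry in template.reports:
        kind, recipient = entry["kind"], entry["recipient"]
        frame = compare_reports.build_report(kind, recipient, inputs)
        dest = out_dir / recipient
        dest.mkdir(exist_ok=True)
        path = dest / f"{kind}.csv"
        frame.to_csv(path, index=False)
        manifest["reports"].append(
            {"kind": kind, "recipient": recipient, "path": str(path), "rows": len(frame)}
        )
    timings["reports"] = time.perf_counter() - t0

    # --- optional validation ----------------------------------------------
    if template.truth_file:
        t0 = time.perf_counter()
        from .synthdata import read_ground_truth

        truth = read_ground_truth(template.truth_file)
        labeled = validation.label_against_truth(results, truth)
        metrics = validation.score_band_metrics(labeled)
        metrics.to_csv(out_dir / "validation.csv", index=False)
        threshold, warning = validation.select_threshold(
            metrics, template.target_precision, alg
        )
        manifest["counts"]["selected_threshold"] = threshold
        manifest["counts"]["threshold_warning"] = warning
        timings["validate"] = time.perf_counter() - t0

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2)
    return manifest
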