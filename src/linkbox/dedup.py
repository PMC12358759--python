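"""Deduplication: cluster shared matches by registry person.

Several Cohort IDs matching the same registry person mean one participant
enrolled at more than one clinic site.  Only shared matches (score at or
above the sharing threshold) may merge persons; sub-threshold matches never
contribute to clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .match_engine import MatchResult

__all__ = ["PersonCluster", "cluster_by_person", "multi_site_summary"]


@dataclass(frozen=True)
class PersonCluster:
    person_id: str
    cohort_ids: tuple[str, ...]
    sites: tuple[str, ...]
    best_score: int

    @property
    def size(self) -> int:
        return len(self.cohort_ids)


def cluster_by_person(
    results: Sequence[MatchResult],
    site_map: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[PersonCluster]:
    """Group shared match results into one cluster per registry person.

    ``results`` must be the shared (score >= threshold) subset of the match
    output; a non-shared result is a usage error.  ``site_map`` maps
    cohort_id to the site IDs where it is enrolled.  Clusters are sorted by
    person_id; cohort_ids within a cluster are sorted.
    """
    site_map = site_map or {}
    groups: dict[str, list[MatchResult]] = {}
    for result in results:
        if not result.shared:
            raise ValueError(
                f"cluster_by_person received a non-shared result for {result.cohort_id}"
            )
        groups.setdefault(result.person_id, []).append(result)

    clusters = []
    for person_id in sorted(groups):
        members = groups[person_id]
        cohort_ids = tuple(sorted({m.cohort_id for m in members}))
        sites: list[str] = []
        for cid in cohort_ids:
            for site in site_map.get(cid, ()):
                if site not in sites:
                    sites.append(site)
        clusters.append(
            PersonCluster(
                person_id=person_id,
                cohort_ids=cohort_ids,
                sites=tuple(sites),
                best_score=max(m.score for m in members),
            )
        )
    return clusters


def multi_site_summary(clusters: Sequence[PersonCluster]):
    """Count multiply-enrolled persons and histogram cluster sizes.

    Returns ``(n_multi, histogram)`` where ``n_multi`` is the number of
    clusters holding two or more Cohort IDs and ``histogram`` maps cluster
    size to cluster count.
    """
    histogram = Counter(c.size for c in clusters)
    n_multi = sum(count for size, count in histogram.items() if size >= 2)
    return n_multi, dict(sorted(histogram.items()))
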