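"""Match validation: labeling against ground truth, precision by score band,
and threshold selection.

After a linkage run, each proposed match is labeled true or false — here
against the synthetic generator's ground truth, standing in for the manual
review (with probabilistic-linkage support) a health department performs on
real data.  Per-score precision, and cumulative precision at or above each
score, drive the choice of the sharing threshold: the smallest defined
score whose cumulative precision still meets the target.

Uncertain labels are kept as their own category and excluded from precision
denominators by default; pass ``uncertain_as_false=True`` to count an
unresolved pair as a false match instead (the stricter review convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .match_engine import MatchAlgorithm, MatchResult, default_algorithm
from .synthdata import GroundTruth

__all__ = [
    "LabeledMatch",
    "LabelingError",
    "label_against_truth",
    "score_band_metrics",
    "select_threshold",
]

TRUE_MATCH = "true_match"
FALSE_MATCH = "false_match"
UNCERTAIN = "uncertain"


class LabelingError(KeyError):
    """A match result's cohort_id is not covered by the ground truth."""


@dataclass(frozen=True)
class LabeledMatch:
    result: MatchResult
    label: str  # true_match | false_match | uncertain

    def __post_init__(self) -> None:
        if self.label not in (TRUE_MATCH, FALSE_MATCH, UNCERTAIN):
            raise ValueError(f"unknown label {self.label!r}")


def label_against_truth(
    results: Sequence[MatchResult], truth: GroundTruth
) -> list[LabeledMatch]:
    """Label each result true_match iff it found the ground-truth person.

    Ground truth is definitive, so no label is ever ``uncertain``.  A
    cohort_id absent from the truth mapping raises :class:`LabelingError`.
    """
    labeled = []
    for result in results:
        if result.cohort_id not in truth.true_pairs:
            raise LabelingError(
                f"cohort_id {result.cohort_id!r} is not covered by the ground truth"
            )
        is_true = truth.true_pairs[result.cohort_id] == result.person_id
        labeled.append(LabeledMatch(result, TRUE_MATCH if is_true else FALSE_MATCH))
    return labeled


def score_band_metrics(
    labeled: Sequence[LabeledMatch], *, uncertain_as_false: bool = False
) -> pd.DataFrame:
    """Per-score counts and precision, with cumulative precision at >= score.

    Returns one row per observed score in descending order with columns
    ``score, n, n_true, n_false, n_uncertain, precision, cum_n, cum_n_true,
    cum_n_false, cum_precision``.  Precision is n_true / (n_true + n_false);
    uncertain pairs are excluded from the denominator unless
    ``uncertain_as_false`` folds them into the false count.
    """
    if not labeled:
        raise ValueError("score_band_metrics requires at least one labeled match")
    counts: dict[int, dict[str, int]] = {}
    for lm in labeled:
        band = counts.setdefault(
            lm.result.score, {TRUE_MATCH: 0, FALSE_MATCH: 0, UNCERTAIN: 0}
        )
        band[lm.label] += 1

    rows = []
    cum_true = cum_false = cum_unc = 0
    for score in sorted(counts, reverse=True):
        band = counts[score]
        n_true, n_unc = band[TRUE_MATCH], band[UNCERTAIN]
        n_false = band[FALSE_MATCH] + (n_unc if uncertain_as_false else 0)
        n_unc_eff = 0 if uncertain_as_false else n_unc
        cum_true += n_true
        cum_false += n_false
        cum_unc += n_unc_eff
        denom = n_true + n_false
        cum_denom = cum_true + cum_false
        rows.append(
            {
                "score": score,
                "n": n_true + n_false + n_unc_eff,
                "n_true": n_true,
                "n_false": n_false,
                "n_uncertain": n_unc_eff,
                "precision": n_true / denom if denom else float("nan"),
                "cum_n": cum_true + cum_false + cum_unc,
                "cum_n_true": cum_true,
                "cum_n_false": cum_false,
                "cum_precision": cum_true / cum_denom if cum_denom else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def select_threshold(
    metrics: pd.DataFrame,
    target_precision: float,
    alg: Optional[MatchAlgorithm] = None,
) -> tuple[int, bool]:
    """Smallest defined score whose cumulative precision meets the target.

    Scans the algorithm's defined scores from the lowest upward and returns
    the first (i.e. smallest) score ``s`` such that cumulative precision at
    >= s meets ``target_precision``; bands with no observations inherit the
    cumulative precision of the band above.  If no score qualifies, returns
    the maximum defined score with the warning flag set.

    Returns ``(score, warning)``.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    alg = alg or default_algorithm()
    observed = metrics.sort_values("score", ascending=False).reset_index(drop=True)

    def cum_precision_at(score: int) -> float:
        at_or_above = observed[observed["score"] >= score]
        if at_or_above.empty:
            return 1.0  # nothing proposed at or above this score: vacuous
        return float(at_or_above.iloc[-1]["cum_precision"])

    for score in sorted(alg.defined_scores):
        value = cum_precision_at(score)
        if value == value and value >= target_precision:  # NaN-safe
            return score, False
    return max(alg.defined_scores), True
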