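"""Examinee scoring against an answer key.

Each of the test's ``n`` items is worth ``100 / n`` points (1.25 points for
the canonical 80-question test), so a perfect paper scores exactly 100.  A
response is correct iff it belongs to the item's accepted set; a missing
response is incorrect.  Scores keep full floating precision — rounding is a
presentation concern.

Deviation values follow the Japanese *hensachi* convention:
``dv = 50 + 10 * (score - mean) / sd`` with the sample (n-1) standard
deviation, so the group mean always sits at 50 and one standard deviation
is worth 10 points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AnalysisError, KeyCoverageError
from .model import AnswerKey, ResponseMatrix, ScoreReport


def score_examinee(
    responses: ResponseMatrix,
    key: AnswerKey,
    rater_id: str | None = None,
    session: int | None = None,
) -> ScoreReport:
    """Score one examinee's responses against *key*.

    *responses* may be pre-restricted, or a full panel together with
    ``rater_id``/``session`` selectors.  All of the key's items are scored;
    items the examinee did not answer count as incorrect (and are tallied in
    ``n_missing``).

    Raises
    ------
    KeyCoverageError
        If the examinee answered an item the key does not cover.
    AnalysisError
        If the restriction does not identify a single rater.
    """
    sub = responses.select(rater_id=rater_id, session=session)
    raters = sub.raters
    if len(raters) > 1:
        raise AnalysisError(
            f"score_examinee needs a single rater; matrix has {len(raters)}"
        )
    rid = rater_id if rater_id is not None else (raters[0] if raters else "")

    uncovered = set(sub.items) - set(key.entries)
    if uncovered:
        raise KeyCoverageError(
            f"items not covered by the answer key: {sorted(uncovered)[:5]}"
        )

    answered = dict(zip(sub.df["item_id"], sub.df["response"]))
    n_items = len(key.entries)
    per_aspect: dict[str, int] = {}
    n_correct = 0
    n_missing = 0
    for item_id, entry in key.entries.items():
        response = answered.get(item_id)
        if response is None:
            n_missing += 1
            correct = False
        else:
            correct = response in entry.accepted
        if correct:
            n_correct += 1
            per_aspect[entry.aspect] = per_aspect.get(entry.aspect, 0) + 1
    return ScoreReport(
        rater_id=rid,
        n_items=n_items,
        n_correct=n_correct,
        n_missing=n_missing,
        total_score=n_correct * (100.0 / n_items),
        per_aspect_correct=per_aspect,
    )


def score_panel(
    responses: ResponseMatrix, key: AnswerKey, session: int | None = None
) -> list[ScoreReport]:
    """Score every rater in the panel; reports ordered by rater id."""
    sub = responses.select(session=session)
    return [score_examinee(sub, key, rater_id=r) for r in sub.raters]


@dataclass(frozen=True)
class CohortSummary:
    mean: float
    sd: float
    per_aspect_mean: Mapping[str, float]


def cohort_summary(reports: Sequence[ScoreReport]) -> CohortSummary:
    """Group mean and sample sd of total scores, plus per-aspect mean correct counts.

    With a single report the sd is NaN (the n-1 estimator is undefined).
    """
    if not reports:
        raise AnalysisError("cohort_summary requires at least one score report")
    scores = np.array([r.total_score for r in reports], dtype=float)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if len(scores) > 1 else float("nan")
    aspects = sorted({a for r in reports for a in r.per_aspect_correct})
    per_aspect = {
        a: float(np.mean([r.per_aspect_correct.get(a, 0) for r in reports]))
        for a in aspects
    }
    return CohortSummary(mean=mean, sd=sd, per_aspect_mean=per_aspect)


def deviation_values(reports: Iterable[ScoreReport]) -> dict[str, float]:
    """Hensachi standard scores, ``50 + 10 * z`` within the group.

    If the group sd is zero every examinee is at the mean, so all deviation
    values are defined as 50; a warning flags the degeneracy.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise AnalysisError("deviation values need at least two examinees")
    scores = np.array([r.total_score for r in reports], dtype=float)
    sd = scores.std(ddof=1)
    if sd == 0.0:
        warnings.warn(
            "all scores identical; deviation values set to 50", stacklevel=2
        )
        return {r.rater_id: 50.0 for r in reports}
    mean = scores.mean()
    return {
        r.rater_id: float(50.0 + 10.0 * (r.total_score - mean) / sd)
        for r in reports
    }
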