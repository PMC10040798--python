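"""Classical test-theory item analysis: difficulty and discrimination.

Difficulty is the proportion of examinees answering an item correctly,
binned as easy (>= 0.85), moderate ([0.50, 0.85)) or hard (< 0.50).

The discrimination index (DI) is the fourfold-point (phi) coefficient
computed from the top and bottom quarters of the total-score ranking.  With
A/B the correct/incorrect counts in the top group and C/D those in the
bottom group,

    phi = (A*D - B*C) / sqrt((A+B) * (C+D) * (A+C) * (B+D)),

which equals the Pearson correlation between the group-membership and
correctness indicator variables on the pooled extreme-group sample.  When
any marginal total is zero — e.g. both groups answered identically — the
coefficient is undefined and the item is binned *undecidable*.  DI bins:
good (phi >= 0.3), fair ([0.1, 0.3)), poor (< 0.1).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .model import AnswerKey, ItemQuality, ResponseMatrix
from .scoring import score_panel

DIFFICULTY_BINS = ("hard", "moderate", "easy")
DI_BINS = ("poor", "fair", "good", "undecidable")


def difficulty_bin(p: float) -> str:
    """Bin a correct-answer proportion; boundaries are lower-inclusive."""
    if not 0.0 <= p <= 1.0:
        raise AnalysisError(f"difficulty must lie in [0, 1], got {p}")
    if p >= 0.85:
        return "easy"
    if p >= 0.50:
        return "moderate"
    return "hard"


def difficulty(correct: Sequence[bool] | np.ndarray) -> tuple[float, str]:
    """Proportion correct and its bin, from a per-examinee indicator vector."""
    arr = np.asarray(correct, dtype=bool)
    if arr.size == 0:
        raise AnalysisError("difficulty requires at least one examinee")
    p = float(arr.mean())
    return p, difficulty_bin(p)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_extreme_groups(
    total_scores: Mapping[str, float],
    fraction: float = 0.25,
    rule: str = "round",
) -> tuple[set[str], set[str]]:
    """Top and bottom score groups for discrimination analysis.

    Group size is ``rule(fraction * n)`` with ``rule`` one of ``round``
    (half-up, the default: 15 examinees give groups of 4), ``floor`` or
    ``ceil``.  Ties at the cut are broken deterministically by a single
    stable sort on (score, examinee id): the bottom group is the first *k*
    entries and the top group the last *k*, so the groups are disjoint
    whenever ``2k <= n``.
    """
    if not 0.0 < fraction <= 0.5:
        raise AnalysisError(f"fraction must lie in (0, 0.5], got {fraction}")
    n = len(total_scores)
    if n < 4:
        raise AnalysisError(f"extreme-group selection needs >= 4 examinees, got {n}")
    sizer = {"round": _round_half_up, "floor": math.floor, "ceil": math.ceil}
    if rule not in sizer:
        raise ValueError(f"rule must be one of {sorted(sizer)}, got {rule!r}")
    k = max(1, int(sizer[rule](fraction * n)))
    if 2 * k > n:
        raise AnalysisError(
            f"group size {k} twice exceeds the cohort size {n}; lower the fraction"
        )
    order = sorted(total_scores, key=lambda r: (total_scores[r], r))
    return set(order[-k:]), set(order[:k])


def phi_discrimination(A: int, B: int, C: int, D: int) -> float | None:
    """Fourfold-point coefficient; ``None`` when a zero marginal makes it undefined."""
    if min(A, B, C, D) < 0:
        raise AnalysisError("fourfold counts must be non-negative")
    denom = (A + B) * (C + D) * (A + C) * (B + D)
    if denom == 0:
        return None
    return (A * D - B * C) / math.sqrt(denom)


def di_bin(phi: float | None) -> str:
    if phi is None:
        return "undecidable"
    if phi >= 0.3:
        return "good"
    if phi >= 0.1:
        return "fair"
    return "poor"


def item_quality_table(
    responses: ResponseMatrix,
    key: AnswerKey,
    session: int | None = None,
    fraction: float = 0.25,
    rule: str = "round",
) -> list[ItemQuality]:
    """Full per-item difficulty/discrimination analysis of a scored test.

    Total scores come from scoring the whole panel against *key*; the
    extreme groups are then fixed once and reused for every item's fourfold
    table.  Missing responses count as incorrect throughout.
    """
    sub = responses.select(session=session)
    reports = score_panel(sub, key)
    if len(reports) < 4:
        raise AnalysisError("item analysis needs at least 4 examinees")
    totals = {r.rater_id: r.total_score for r in reports}
    top, bottom = select_extreme_groups(totals, fraction=fraction, rule=rule)

    # (rater, item) -> response lookup
    answered: dict[tuple[str, str], str] = dict(
        zip(zip(sub.df["rater_id"], sub.df["item_id"]), sub.df["response"])
    )
    raters = sub.raters
    out: list[ItemQuality] = []
    for item_id in sorted(key.entries):
        entry = key.entries[item_id]
        correct = {
            r: answered.get((r, item_id)) in entry.accepted for r in raters
        }
        p, dbin = difficulty([correct[r] for r in raters])
        A = sum(correct[r] for r in top)
        B = len(top) - A
        C = sum(correct[r] for r in bottom)
        D = len(bottom) - C
        phi = phi_discrimination(A, B, C, D)
        out.append(
            ItemQuality(
                item_id=item_id,
                aspect=entry.aspect,
                difficulty=p,
                difficulty_bin=dbin,
                phi=phi,
                di_bin=di_bin(phi),
                fourfold=(A, B, C, D),
            )
        )
    return out


def quality_frame(qualities: Sequence[ItemQuality]) -> pd.DataFrame:
    """Tidy one-row-per-item frame of an item-quality analysis."""
    return pd.DataFrame(
        {
            "item_id": [q.item_id for q in qualities],
            "aspect": [q.aspect for q in qualities],
            "difficulty": [q.difficulty for q in qualities],
            "difficulty_bin": [q.difficulty_bin for q in qualities],
            "phi": [np.nan if q.phi is None else q.phi for q in qualities],
            "di_bin": [q.di_bin for q in qualities],
            "A": [q.fourfold[0] for q in qualities],
            "B": [q.fourfold[1] for q in qualities],
            "C": [q.fourfold[2] for q in qualities],
            "D": [q.fourfold[3] for q in qualities],
        }
    )


def quality_crosstab(qualities: Sequence[ItemQuality]) -> pd.DataFrame:
    """Counts of items per (difficulty bin x DI bin) cell."""
    df = quality_frame(qualities)
    tab = pd.crosstab(df["di_bin"], df["difficulty_bin"])
    tab = tab.reindex(index=list(DI_BINS), columns=list(DIFFICULTY_BINS), fill_value=0)
    tab.index.name = "di_bin"
    tab.columns.name = "difficulty_bin"
    return tab
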