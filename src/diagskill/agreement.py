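"""Rater agreement: intrarater match rates and Gwet's AC1.

Gwet's AC1 is a chance-corrected agreement coefficient for multiple raters
assigning items to nominal categories.  Unlike kappa-type statistics it
stays stable under skewed category prevalence, which matters here: most
tongue images are "normal" on most aspects.

With ``r_iq`` raters placing item *i* in category *q* and ``r_i`` raters
rating item *i*:

* observed agreement  ``p_a = mean over items with r_i >= 2 of
  sum_q r_iq (r_iq - 1) / (r_i (r_i - 1))`` — the probability that two
  randomly chosen raters of the same item agree;
* category prevalence ``pi_q = mean over items of r_iq / r_i``;
* chance agreement    ``p_e = (1 / (Q - 1)) * sum_q pi_q (1 - pi_q)``;
* ``AC1 = (p_a - p_e) / (1 - p_e)``.

``Q`` defaults to the declared vocabulary size of the aspect —
"not_applicable" is a selectable answer and counts as a category — with an
option to restrict to observed categories.

Confidence intervals use a leave-one-item-out jackknife with normal
quantiles, clipped to [-1, 1].

Pooling across aspects ("all images") treats every (image, aspect) question
as an item: pooled ``p_a`` is the item-weighted mean of per-item agreement,
and pooled ``p_e`` the item-weighted mean of the per-aspect chance
agreements, each computed within its own category space.

Coefficients are interpreted on the conventional verbal scale
(poor < 0 <= slight < 0.2 <= fair < 0.4 <= moderate < 0.6 <= substantial
< 0.8 <= almost perfect); band boundaries are lower-inclusive.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .model import AgreementResult, MatchRateResult, ResponseMatrix

LANDIS_KOCH_BANDS = (
    "poor",
    "slight",
    "fair",
    "moderate",
    "substantial",
    "almost perfect",
)


def interpret_landis_koch(coefficient: float) -> str:
    """Verbal interpretation band of an agreement coefficient.

    Bands are half-open and lower-inclusive at 0, 0.2, 0.4, 0.6 and 0.8, so
    a coefficient of exactly 0.40 reads "moderate".
    """
    c = float(coefficient)
    if not -1.0 - 1e-9 <= c <= 1.0 + 1e-9:
        raise AnalysisError(f"agreement coefficient must lie in [-1, 1], got {c}")
    if c < 0.0:
        return "poor"
    if c < 0.2:
        return "slight"
    if c < 0.4:
        return "fair"
    if c < 0.6:
        return "moderate"
    if c < 0.8:
        return "substantial"
    return "almost perfect"


def _block_pa_pe(counts: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Per-item pairwise agreement, chance agreement, and item count.

    *counts* is an items x Q vote matrix for one category space.  Items with
    fewer than two raters contribute to prevalence but get NaN agreement.
    """
    counts = np.asarray(counts, dtype=float)
    r_i = counts.sum(axis=1)
    keep = r_i >= 1
    counts, r_i = counts[keep], r_i[keep]
    if counts.shape[0] == 0:
        raise AnalysisError("no rated items in panel")
    Q = counts.shape[1]
    if Q < 2:
        raise AnalysisError("chance agreement undefined with fewer than 2 categories")
    with np.errstate(invalid="ignore", divide="ignore"):
        pa_i = (counts * (counts - 1)).sum(axis=1) / (r_i * (r_i - 1))
    pa_i[r_i < 2] = np.nan
    pi = (counts / r_i[:, None]).mean(axis=0)
    pe = float((pi * (1.0 - pi)).sum() / (Q - 1))
    return pa_i, pe, counts.shape[0]


def _ac1_from_blocks(blocks: Sequence[np.ndarray]) -> tuple[float, float, float]:
    """(ac1, p_a, p_e) for one or more category-space blocks of items."""
    pa_parts: list[np.ndarray] = []
    pe_weighted = 0.0
    n_total = 0
    for counts in blocks:
        pa_i, pe, n = _block_pa_pe(counts)
        pa_parts.append(pa_i)
        pe_weighted += pe * n
        n_total += n
    pa_all = np.concatenate(pa_parts)
    if np.isnan(pa_all).all():
        raise AnalysisError("every item has fewer than 2 raters; agreement undefined")
    p_a = float(np.nanmean(pa_all))
    p_e = pe_weighted / n_total
    if p_e >= 1.0:
        raise AnalysisError("chance agreement is 1; AC1 undefined")
    return (p_a - p_e) / (1.0 - p_e), p_a, p_e


def _panel_blocks(
    panel: ResponseMatrix, aspect: str | None, categories: str
) -> list[np.ndarray]:
    aspects = [aspect] if aspect is not None else list(panel.aspects)
    if not aspects:
        raise AnalysisError("panel contains no responses")
    blocks = []
    for a in aspects:
        counts = panel.category_counts(a)
        if counts.empty:
            continue
        mat = counts.to_numpy()
        if categories == "observed":
            mat = mat[:, mat.sum(axis=0) > 0]
        elif categories != "declared":
            raise ValueError("categories must be 'declared' or 'observed'")
        blocks.append(mat)
    if not blocks:
        raise AnalysisError("panel contains no responses for the requested aspect")
    return blocks


def gwet_ac1(
    panel: ResponseMatrix,
    aspect: str | None = None,
    level: float = 0.95,
    categories: str = "declared",
    ci: str = "jackknife",
) -> AgreementResult:
    """Gwet's AC1 for a rater panel, with jackknife confidence interval.

    Parameters
    ----------
    panel
        Responses of >= 2 raters (restrict sessions upstream if needed).
    aspect
        Compute for one aspect, or pool every aspect's items (default).
    categories
        ``"declared"`` uses the full aspect vocabulary as the category
        space Q; ``"observed"`` restricts to categories actually used.
    ci
        Only ``"jackknife"`` (leave-one-item-out, normal quantiles).
    """
    if ci != "jackknife":
        raise ValueError(f"unsupported CI method {ci!r}")
    if not 0.0 < level < 1.0:
        raise AnalysisError(f"confidence level must lie in (0, 1), got {level}")
    blocks = _panel_blocks(panel, aspect, categories)
    ac1, p_a, p_e = _ac1_from_blocks(blocks)

    # leave-one-item-out pseudo-estimates
    thetas: list[float] = []
    for b_idx, counts in enumerate(blocks):
        for row in range(counts.shape[0]):
            reduced = [
                np.delete(c, row, axis=0) if j == b_idx else c
                for j, c in enumerate(blocks)
            ]
            if sum(c.shape[0] for c in reduced) == 0:
                continue
            try:
                thetas.append(_ac1_from_blocks(reduced)[0])
            except AnalysisError:
                continue
    n_items = sum(c.shape[0] for c in blocks)
    if len(thetas) >= 2:
        th = np.asarray(thetas)
        m = len(th)
        se = float(np.sqrt((m - 1) / m * ((th - th.mean()) ** 2).sum()))
        z = stats.norm.ppf(0.5 + level / 2.0)
        ci_low = max(-1.0, ac1 - z * se)
        ci_high = min(1.0, ac1 + z * se)
    else:
        ci_low, ci_high = -1.0, 1.0
    ci_low, ci_high = min(ci_low, ac1), max(ci_high, ac1)

    return AgreementResult(
        ac1=float(ac1),
        p_a=float(p_a),
        p_e=float(p_e),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=level,
        n_items=n_items,
        n_raters=len(panel.raters),
        n_categories=max(c.shape[1] for c in blocks),
        interpretation=interpret_landis_koch(float(np.clip(ac1, -1.0, 1.0))),
    )


def agreement_table(
    panel: ResponseMatrix, level: float = 0.95, categories: str = "declared"
) -> pd.DataFrame:
    """Per-aspect AC1 plus the pooled "all" row, as a tidy frame."""
    rows = []
    for scope in list(panel.aspects) + ["all"]:
        res = gwet_ac1(
            panel,
            aspect=None if scope == "all" else scope,
            level=level,
            categories=categories,
        )
        rows.append(
            {
                "scope": scope,
                "ac1": res.ac1,
                "p_a": res.p_a,
                "p_e": res.p_e,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "band": res.interpretation,
                "n_items": res.n_items,
                "n_raters": res.n_raters,
            }
        )
    return pd.DataFrame(rows)


def intrarater_match(
    session1: ResponseMatrix, session2: ResponseMatrix
) -> MatchRateResult:
    """Test-retest diagnostic match rates between two sessions.

    A match is exact equality of the two single responses to the same
    (rater, item); items answered in only one session are ignored.  The
    per-aspect rates average each rater's aspect-level proportion; the
    overall mean and sample sd are taken over the per-rater proportions.
    Raters with no overlapping items are omitted with a warning.
    """
    left = session1.df[["rater_id", "item_id", "aspect", "response"]]
    right = session2.df[["rater_id", "item_id", "aspect", "response"]]
    merged = left.merge(
        right, on=["rater_id", "item_id", "aspect"], suffixes=("_1", "_2")
    )
    all_raters = set(session1.raters) | set(session2.raters)
    omitted = sorted(all_raters - set(merged["rater_id"].unique()))
    if omitted:
        warnings.warn(
            f"raters with no overlapping items omitted: {omitted}", stacklevel=2
        )
    if merged.empty:
        raise AnalysisError("no overlapping (rater, item) pairs between sessions")
    merged["match"] = merged["response_1"] == merged["response_2"]

    per_rater = merged.groupby("rater_id")["match"].mean().to_dict()
    per_aspect = (
        merged.groupby(["aspect", "rater_id"])["match"]
        .mean()
        .groupby("aspect")
        .mean()
        .to_dict()
    )
    rates = np.array(list(per_rater.values()), dtype=float)
    return MatchRateResult(
        per_rater={k: float(v) for k, v in per_rater.items()},
        per_aspect={k: float(v) for k, v in per_aspect.items()},
        overall_mean=float(rates.mean()),
        overall_sd=float(rates.std(ddof=1)) if len(rates) > 1 else float("nan"),
    )


def intrarater_match_sessions(
    matrix: ResponseMatrix, first: int = 1, second: int = 2
) -> MatchRateResult:
    """Convenience wrapper splitting one matrix by session number."""
    return intrarater_match(matrix.select(session=first), matrix.select(session=second))
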