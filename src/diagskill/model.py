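"""Core domain containers.

The central object is the :class:`ResponseMatrix`: a long-format table of
categorical diagnoses keyed by (rater, item, aspect, session).  An *item* is
one question, i.e. one (image, aspect) pair — a 10-image test over 8 aspects
has 80 items.  Missingness is represented by record absence, never by a
sentinel category.

:class:`AnswerKey` maps each item to a non-empty *accepted set* of
categories.  Multi-category accepted sets arise naturally from tied majority
votes ("light_red or purple"); any member counts as correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    SchemaError,
    VocabularyError,
)
from .vocab import ASPECTS, vocabulary

RESPONSE_COLUMNS = ("rater_id", "item_id", "aspect", "session", "response")
_KEY_COLUMNS = ["rater_id", "item_id", "aspect", "session"]


@dataclass(frozen=True)
class ResponseMatrix:
    """Validated long-format panel of categorical responses.

    Wraps a :class:`pandas.DataFrame` with columns
    ``rater_id, item_id, aspect, session, response``.  Construct via
    :meth:`from_frame` (or :func:`diagskill.io.read_responses`), which
    enforces vocabulary membership and key uniqueness; downstream code can
    therefore never observe an out-of-vocabulary category.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"response table is missing columns {missing_cols}")
        df = df.loc[:, list(RESPONSE_COLUMNS)].copy()
        # absent response cells mean "no record": drop them up front
        df = df[df["response"].notna() & (df["response"].astype(str).str.len() > 0)]
        df["rater_id"] = df["rater_id"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        df["aspect"] = df["aspect"].astype(str)
        df["response"] = df["response"].astype(str)
        try:
            df["session"] = df["session"].astype(int)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"session column is not integer-valued: {exc}") from None
        if (df["session"] < 1).any():
            bad = df.index[df["session"] < 1][0]
            raise SchemaError(f"session must be a positive integer (row {bad})")

        unknown = set(df["aspect"]) - set(ASPECTS)
        if unknown:
            raise SchemaError(f"unknown aspect name(s): {sorted(unknown)}")
        for aspect, sub in df.groupby("aspect", sort=False):
            vocab = set(vocabulary(str(aspect)))
            bad_mask = ~sub["response"].isin(vocab)
            if bad_mask.any():
                row = sub[bad_mask].iloc[0]
                raise VocabularyError(
                    f"response {row['response']!r} is not in the {aspect} "
                    f"vocabulary (rater {row['rater_id']}, item {row['item_id']}, "
                    f"session {row['session']})"
                )
        dup = df.duplicated(subset=_KEY_COLUMNS, keep=False)
        if dup.any():
            first = df[dup].iloc[0]
            raise DuplicateRecordError(
                "duplicate (rater, item, aspect, session) tuple, e.g. "
                f"({first['rater_id']}, {first['item_id']}, {first['aspect']}, "
                f"{first['session']})"
            )
        df = df.reset_index(drop=True)
        return cls(df)

    # ------------------------------------------------------------------ views
    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["rater_id"].unique()))

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["item_id"].unique()))

    @property
    def aspects(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["aspect"].unique()))

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(sorted(self.df["session"].unique()))

    def __len__(self) -> int:
        return len(self.df)

    def select(
        self,
        rater_id: str | None = None,
        session: int | None = None,
        aspect: str | None = None,
    ) -> "ResponseMatrix":
        """Restrict to one rater / session / aspect (any subset of the three)."""
        mask = pd.Series(True, index=self.df.index)
        if rater_id is not None:
            mask &= self.df["rater_id"] == rater_id
        if session is not None:
            mask &= self.df["session"] == session
        if aspect is not None:
            mask &= self.df["aspect"] == aspect
        return ResponseMatrix(self.df[mask].reset_index(drop=True))

    def item_aspects(self) -> dict[str, str]:
        """Map each item to its (single) aspect."""
        pairs = self.df[["item_id", "aspect"]].drop_duplicates()
        counts = pairs["item_id"].value_counts()
        if (counts > 1).any():
            bad = counts.index[counts > 1][0]
            raise SchemaError(f"item {bad!r} appears under more than one aspect")
        return dict(zip(pairs["item_id"], pairs["aspect"]))

    def category_counts(self, aspect: str) -> pd.DataFrame:
        """Items × categories vote-count table for one aspect.

        Columns are the full declared vocabulary of *aspect*, in order;
        rows are the items observed for that aspect (sorted).
        """
        sub = self.df[self.df["aspect"] == aspect]
        vocab = vocabulary(aspect)
        counts = pd.crosstab(sub["item_id"], sub["response"])
        counts = counts.reindex(columns=list(vocab), fill_value=0).sort_index()
        counts.columns.name = None
        counts.index.name = "item_id"
        return counts.astype(np.int64)


@dataclass(frozen=True)
class KeyEntry:
    """One answer-key entry: the item's aspect and its accepted categories."""

    aspect: str
    accepted: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        vocab = set(vocabulary(self.aspect))
        if not self.accepted:
            raise VocabularyError("accepted set must contain at least one category")
        outside = set(self.accepted) - vocab
        if outside:
            raise VocabularyError(
                f"accepted categories {sorted(outside)} are not in the "
                f"{self.aspect} vocabulary"
            )


@dataclass(frozen=True)
class AnswerKey:
    """Answer key: ``item_id -> KeyEntry``."""

    entries: Mapping[str, KeyEntry]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, item_id: str) -> KeyEntry:
        return self.entries[item_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnswerKey):
            return NotImplemented
        return dict(self.entries) == dict(other.entries)

    def widen(self, item_id: str, extra: Iterable[str]) -> "AnswerKey":
        """Return a new key with *extra* categories added to one accepted set."""
        entry = self.entries[item_id]
        new_entry = replace(entry, accepted=entry.accepted | frozenset(extra))
        entries = dict(self.entries)
        entries[item_id] = new_entry
        return AnswerKey(entries)


@dataclass(frozen=True)
class ScoreReport:
    """Per-examinee scoring result on the 0-100 point scale."""

    rater_id: str
    n_items: int
    n_correct: int
    n_missing: int
    total_score: float
    per_aspect_correct: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_aspect_correct", dict(self.per_aspect_correct))


@dataclass(frozen=True)
class ItemQuality:
    """Per-item difficulty and discrimination summary."""

    item_id: str
    aspect: str
    difficulty: float
    difficulty_bin: str  # hard | moderate | easy
    phi: float | None  # None when undecidable
    di_bin: str  # poor | fair | good | undecidable
    fourfold: tuple[int, int, int, int]  # (A, B, C, D)


@dataclass(frozen=True)
class MatchRateResult:
    """Intrarater (test-retest) diagnostic match rates."""

    per_rater: Mapping[str, float]
    per_aspect: Mapping[str, float]
    overall_mean: float
    overall_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_rater", dict(self.per_rater))
        object.__setattr__(self, "per_aspect", dict(self.per_aspect))


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected multi-rater agreement (Gwet's AC1)."""

    ac1: float
    p_a: float
    p_e: float
    ci_low: float
    ci_high: float
    level: float
    n_items: int
    n_raters: int
    n_categories: int
    interpretation: str
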