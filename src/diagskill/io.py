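"""Readers and writers for the package's tabular formats.

Responses travel as long CSV (``rater_id,item_id,aspect,session,response``),
answer keys as JSON keyed by item id, cohort tables as plain CSV.  All
formats are UTF-8 text; every read validates against the aspect
vocabularies so malformed files fail at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError, VocabularyError
from .model import RESPONSE_COLUMNS, AnswerKey, KeyEntry, ResponseMatrix


def read_responses(path: str | Path) -> ResponseMatrix:
    """Read a long-format response CSV into a validated :class:`ResponseMatrix`.

    A file containing only the header yields an empty matrix.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"response file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: header is missing columns {missing}")
    return ResponseMatrix.from_frame(df)


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    df = matrix.df.sort_values(
        ["rater_id", "item_id", "aspect", "session"], kind="stable"
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_key(path: str | Path) -> AnswerKey:
    """Read an answer key from JSON.

    Expected shape::

        {"img1_body_color": {"aspect": "body_color",
                             "accepted": ["light_red"],
                             "provenance": "15-rater majority"}, ...}
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"answer key not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: answer key must be a JSON object keyed by item_id")
    entries: dict[str, KeyEntry] = {}
    for item_id, spec in raw.items():
        if not isinstance(spec, dict) or "aspect" not in spec or "accepted" not in spec:
            raise SchemaError(
                f"{path}: entry {item_id!r} must have 'aspect' and 'accepted' fields"
            )
        accepted = spec["accepted"]
        if not isinstance(accepted, list) or not accepted:
            raise VocabularyError(
                f"{path}: entry {item_id!r} has an empty or non-list accepted set"
            )
        entries[item_id] = KeyEntry(
            aspect=spec["aspect"],
            accepted=frozenset(str(c) for c in accepted),
            provenance=str(spec.get("provenance", "")),
        )
    return AnswerKey(entries)


def write_key(key: AnswerKey, path: str | Path) -> None:
    payload = {
        item_id: {
            "aspect": entry.aspect,
            "accepted": sorted(entry.accepted),
            "provenance": entry.provenance,
        }
        for item_id, entry in sorted(key.entries.items())
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, ensure_ascii=False, sort_keys=True)
        fh.write("\n")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort covariate table (one row per examinee).

    Requires ``examinee_id``, ``group`` (``correct``/``incorrect``) and
    ``total_score`` columns; any further columns are treated as categorical
    covariates.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    required = ["examinee_id", "group", "total_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cohort table is missing columns {missing}")
    bad_group = set(df["group"].astype(str)) - {"correct", "incorrect"}
    if bad_group:
        raise SchemaError(f"{path}: group labels must be correct/incorrect, got {sorted(bad_group)}")
    scores = pd.to_numeric(df["total_score"], errors="coerce")
    if scores.isna().any() or (scores < 0).any() or (scores > 100).any():
        raise SchemaError(f"{path}: total_score must be numeric within [0, 100]")
    df["total_score"] = scores
    return df
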