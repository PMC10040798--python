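"""Majority-vote answer keys and key comparison.

The consensus answer for an item is the set of categories attaining the
maximum vote count over the panel — a plurality rule with no quorum: with
four to six categories the winner may hold well under half the votes, and
ties produce multi-category accepted sets ("light_red or purple"), any
member of which scores as correct.

``key_change_rate`` compares two keys over the same item universe.  An item
counts as *changed* when its accepted sets differ **as sets**, which covers
both outright answer replacement and tie widening/narrowing; pass
``change_def="disjoint"`` to count only items whose accepted sets share no
category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .errors import AnalysisError, ItemUniverseError
from .model import AnswerKey, KeyEntry, ResponseMatrix


def majority_key(
    panel: ResponseMatrix,
    session: int | None = None,
    expected_items: Iterable[str] | None = None,
) -> AnswerKey:
    """Build a plurality-vote answer key from a rater panel.

    Parameters
    ----------
    panel
        Responses of the voting panel; restricted to *session* if given.
    expected_items
        Optional item universe; items in it that received zero votes are
        excluded from the key with a warning.
    """
    sub = panel.select(session=session)
    if len(sub) == 0:
        raise AnalysisError("majority_key: panel has no responses")
    item_aspects = sub.item_aspects()
    n_raters = len(sub.raters)
    tag = f"majority of {n_raters} raters" + (
        f", session {session}" if session is not None else ""
    )

    entries: dict[str, KeyEntry] = {}
    for aspect in sub.aspects:
        counts = sub.category_counts(aspect)
        for item_id, votes in counts.iterrows():
            top = votes.max()
            if top == 0:
                continue
            accepted = frozenset(votes.index[votes == top])
            entries[str(item_id)] = KeyEntry(
                aspect=item_aspects[str(item_id)], accepted=accepted, provenance=tag
            )
    if expected_items is not None:
        silent = set(expected_items) - set(entries)
        if silent:
            warnings.warn(
                f"items with zero responses excluded from key: {sorted(silent)}",
                stacklevel=2,
            )
    return AnswerKey(entries)


@dataclass(frozen=True)
class KeyChangeResult:
    n_changed: int
    n_items: int
    rate: float
    changed_items: tuple[str, ...]


def key_change_rate(
    old: AnswerKey, new: AnswerKey, change_def: str = "set"
) -> KeyChangeResult:
    """Count items whose accepted answer differs between two keys.

    ``change_def="set"`` (default): changed iff the accepted sets are
    unequal.  ``change_def="disjoint"``: changed iff they share no category.
    The comparison is symmetric in its arguments.
    """
    if change_def not in ("set", "disjoint"):
        raise ValueError(f"change_def must be 'set' or 'disjoint', got {change_def!r}")
    old_items, new_items = set(old.entries), set(new.entries)
    if old_items != new_items:
        diff = sorted(old_items ^ new_items)
        raise ItemUniverseError(
            f"keys cover different item universes; symmetric difference: {diff}"
        )
    changed = []
    for item_id in sorted(old_items):
        a, b = old[item_id].accepted, new[item_id].accepted
        if (change_def == "set" and a != b) or (
            change_def == "disjoint" and not (a & b)
        ):
            changed.append(item_id)
    n = len(old_items)
    return KeyChangeResult(
        n_changed=len(changed),
        n_items=n,
        rate=len(changed) / n if n else 0.0,
        changed_items=tuple(changed),
    )
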