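"""End-to-end study pipeline.

Chains the analysis stages on one response matrix: score every rater and
compute deviation values, rebuild the majority-vote key and quantify answer
change against the supplied key, run the item difficulty/discrimination
analysis, compute per-aspect and pooled AC1, and — when a first-diagnosis
matrix is supplied — the intrarater match rates.  Every bundle carries a
manifest (input checksums, parameters, package version) so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import agreement_table, intrarater_match
from .consensus import key_change_rate, majority_key
from .io import write_key
from .item_analysis import item_quality_table, quality_crosstab, quality_frame
from .model import AnswerKey, ResponseMatrix
from .scoring import cohort_summary, deviation_values, score_panel


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class StudyBundle:
    out_dir: Path
    files: tuple[str, ...]


def run_study1(
    responses: ResponseMatrix,
    key: AnswerKey,
    out_dir: str | Path,
    first_diagnosis: ResponseMatrix | None = None,
    session: int = 2,
    level: float = 0.95,
    input_paths: dict[str, str | Path] | None = None,
) -> StudyBundle:
    """Run the full assessment pipeline and write a CSV/JSON report bundle.

    Parameters
    ----------
    responses
        Test-session panel (scored against *key*; AC1 over the same data).
    key
        Answer key the test was graded with (e.g. the original 5-rater key).
    first_diagnosis
        Optional earlier session of (a subset of) the same raters, for the
        intrarater match-rate stage.
    session
        Session number of the test responses inside *responses*.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    test = responses.select(session=session) if session in responses.sessions else responses

    # --- scoring -----------------------------------------------------------
    reports = score_panel(test, key)
    dvs = deviation_values(reports) if len(reports) >= 2 else {}
    scores = pd.DataFrame(
        {
            "rater_id": [r.rater_id for r in reports],
            "n_correct": [r.n_correct for r in reports],
            "n_missing": [r.n_missing for r in reports],
            "total_score": [r.total_score for r in reports],
            "deviation_value": [dvs.get(r.rater_id) for r in reports],
        }
    )
    scores.to_csv(out / "scores.csv", index=False, lineterminator="\n")
    files.append("scores.csv")

    radar = pd.DataFrame(
        [
            {"rater_id": r.rater_id, "aspect": a, "correct_count": c}
            for r in reports
            for a, c in sorted(r.per_aspect_correct.items())
        ]
    )
    radar.to_csv(out / "radar.csv", index=False, lineterminator="\n")
    files.append("radar.csv")

    summary = cohort_summary(reports)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "mean_score": summary.mean,
                "sd_score": summary.sd,
                "per_aspect_mean_correct": summary.per_aspect_mean,
                "n_examinees": len(reports),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    files.append("summary.json")

    # --- consensus ---------------------------------------------------------
    consensus = majority_key(test)
    write_key(consensus, out / "majority_key.json")
    files.append("majority_key.json")
    change = key_change_rate(key, consensus)
    pd.DataFrame(
        {
            "item_id": list(change.changed_items),
            "old_accepted": ["|".join(sorted(key[i].accepted)) for i in change.changed_items],
            "new_accepted": [
                "|".join(sorted(consensus[i].accepted)) for i in change.changed_items
            ],
        }
    ).to_csv(out / "key_changes.csv", index=False, lineterminator="\n")
    files.append("key_changes.csv")

    # --- item analysis -----------------------------------------------------
    qualities = item_quality_table(test, key)
    quality_frame(qualities).to_csv(out / "items.csv", index=False, lineterminator="\n")
    quality_crosstab(qualities).to_csv(out / "items_crosstab.csv", lineterminator="\n")
    files += ["items.csv", "items_crosstab.csv"]

    # --- agreement ---------------------------------------------------------
    agreement_table(test, level=level).to_csv(
        out / "agreement.csv", index=False, lineterminator="\n"
    )
    files.append("agreement.csv")

    if first_diagnosis is not None:
        first = first_diagnosis
        if len(first.sessions) > 1:  # a two-session file: the first session is the earlier diagnosis
            first = first.select(session=min(first.sessions))
        match = intrarater_match(first, test)
        pd.DataFrame(
            [{"scope": f"rater:{r}", "match_rate": v} for r, v in sorted(match.per_rater.items())]
            + [{"scope": f"aspect:{a}", "match_rate": v} for a, v in sorted(match.per_aspect.items())]
            + [
                {"scope": "overall_mean", "match_rate": match.overall_mean},
                {"scope": "overall_sd", "match_rate": match.overall_sd},
            ]
        ).to_csv(out / "match.csv", index=False, lineterminator="\n")
        files.append("match.csv")

    manifest = {
        "tool": "diagskill",
        "version": __version__,
        "parameters": {
            "session": session,
            "confidence_level": level,
            "n_raters": len(test.raters),
            "n_items": len(key.entries),
        },
        "inputs": {
            name: _sha256(Path(p)) for name, p in (input_paths or {}).items()
        },
        "outputs": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append("manifest.json")
    return StudyBundle(out_dir=out, files=tuple(files))
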