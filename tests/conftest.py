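import pandas as pd
import pytest

from diagskill.model import AnswerKey, KeyEntry, ResponseMatrix
from diagskill.simulate import PanelConfig, simulate_panel


def make_matrix(rows):
    """Build a ResponseMatrix from (rater, item, aspect, session, response) tuples."""
    return ResponseMatrix.from_frame(
        pd.DataFrame(
            rows, columns=["rater_id", "item_id", "aspect", "session", "response"]
        )
    )


def make_key(entries, provenance=""):
    """Build an AnswerKey from {item_id: (aspect, accepted-iterable)}."""
    return AnswerKey(
        {
            item: KeyEntry(aspect=a, accepted=frozenset(acc), provenance=provenance)
            for item, (a, acc) in entries.items()
        }
    )


@pytest.fixture(scope="session")
def study1_panel():
    """Canonical study-shaped simulated panel: 10 images x 8 aspects x 15 raters."""
    return simulate_panel(PanelConfig(seed=11))
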