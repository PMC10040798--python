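"""Gwet's AC1, Landis-Koch interpretation, intrarater match rates."""

import numpy as np
import pytest

from diagskill import (
    gwet_ac1,
    interpret_landis_koch,
    intrarater_match,
    intrarater_match_sessions,
)
from diagskill.agreement import _ac1_from_blocks
from diagskill.errors import AnalysisError
from diagskill.simulate import PanelConfig, simulate_panel
from diagskill.vocab import vocabulary

from conftest import make_matrix


def naive_ac1(counts):
    """Triple-loop evaluation of the AC1 definitions (independent oracle).

    *counts* is a list of per-item {category: votes} dicts over a common
    category list attached as ``counts.categories`` is avoided — pass a
    (list_of_dicts, categories) tuple instead.
    """
    items, categories = counts
    Q = len(categories)
    pa_terms = []
    for votes in items:
        r_i = sum(votes.get(c, 0) for c in categories)
        if r_i >= 2:
            s = 0.0
            for c in categories:
                r = votes.get(c, 0)
                s += r * (r - 1)
            pa_terms.append(s / (r_i * (r_i - 1)))
    p_a = sum(pa_terms) / len(pa_terms)
    p_e = 0.0
    for c in categories:
        pi = 0.0
        n = 0
        for votes in items:
            r_i = sum(votes.get(cc, 0) for cc in categories)
            if r_i >= 1:
                pi += votes.get(c, 0) / r_i
                n += 1
        pi /= n
        p_e += pi * (1 - pi)
    p_e /= Q - 1
    return (p_a - p_e) / (1 - p_e), p_a, p_e


def _panel_from_assignments(assignments, aspect="tooth_marks"):
    """assignments: items x raters array of category indices."""
    vocab = vocabulary(aspect)
    rows = []
    for i, item_votes in enumerate(assignments):
        for r, cat_idx in enumerate(item_votes):
            rows.append((f"r{r:02d}", f"i{i:02d}", aspect, 1, vocab[int(cat_idx)]))
    return make_matrix(rows)


class TestGwetAC1:
    def test_unanimous_panel_is_perfect_agreement(self):
        panel = _panel_from_assignments(np.zeros((6, 4)))
        res = gwet_ac1(panel, aspect="tooth_marks")
        assert res.p_a == 1.0
        assert res.ac1 == 1.0
        assert res.interpretation == "almost perfect"
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_hand_worked_two_category_example(self):
        """3 raters, 4 items, 2 categories, per-item first-category counts
        (3,3,2,1): p_a=2/3, pi=(3/4,1/4), p_e=3/8, AC1=7/15."""
        ac1, p_a, p_e = _ac1_from_blocks([np.array([[3, 0], [3, 0], [2, 1], [1, 2]])])
        assert p_a == pytest.approx(2 / 3, abs=1e-15)
        assert p_e == pytest.approx(3 / 8, abs=1e-15)
        assert ac1 == pytest.approx(7 / 15, abs=1e-15)

    def test_hand_worked_example_through_public_api(self):
        # same panel expressed as responses; Q restricted to observed categories
        assignments = [[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 1, 1]]
        panel = _panel_from_assignments(assignments)
        res = gwet_ac1(panel, aspect="tooth_marks", categories="observed")
        assert res.ac1 == pytest.approx(7 / 15, abs=1e-12)
        assert res.n_categories == 2
        assert res.interpretation == "moderate"

    def test_matches_naive_oracle_on_random_panels(self):
        """Vectorized AC1 equals the definitional triple loop to 1e-12."""
        rng = np.random.default_rng(2024)
        vocab = vocabulary("tooth_marks")
        for _ in range(100):
            n_raters = rng.integers(2, 6)
            n_items = rng.integers(2, 9)
            assignments = rng.integers(0, 4, size=(n_items, n_raters))
            panel = _panel_from_assignments(assignments)
            res = gwet_ac1(panel, aspect="tooth_marks")
            items = [
                {vocab[c]: int((assignments[i] == c).sum()) for c in range(4)}
                for i in range(n_items)
            ]
            expected, p_a, p_e = naive_ac1((items, list(vocab)))
            assert res.ac1 == pytest.approx(expected, abs=1e-12)
            assert res.p_a == pytest.approx(p_a, abs=1e-12)
            assert res.p_e == pytest.approx(p_e, abs=1e-12)

    def test_rater_relabeling_and_item_order_invariance(self):
        rng = np.random.default_rng(5)
        assignments = rng.integers(0, 4, size=(8, 4))
        panel = _panel_from_assignments(assignments)
        res1 = gwet_ac1(panel, aspect="tooth_marks")
        df = panel.df.copy()
        df["rater_id"] = df["rater_id"].map(
            {"r00": "zebra", "r01": "yak", "r02": "xerus", "r03": "wolf"}
        )
        df = df.sample(frac=1.0, random_state=0)
        from diagskill.model import ResponseMatrix

        res2 = gwet_ac1(ResponseMatrix.from_frame(df), aspect="tooth_marks")
        assert res2.ac1 == pytest.approx(res1.ac1, abs=1e-15)
        assert (res2.ci_low, res2.ci_high) == pytest.approx((res1.ci_low, res1.ci_high))

    def test_ci_brackets_point_estimate(self, study1_panel):
        _, matrix = study1_panel
        res = gwet_ac1(matrix.select(session=2), aspect="body_color")
        assert -1.0 <= res.ci_low <= res.ac1 <= res.ci_high <= 1.0

    def test_pooled_equals_item_weighted_per_aspect_combination(self, study1_panel):
        """The pooling convention: pooled p_a / p_e are item-count-weighted
        means of the per-aspect values."""
        _, matrix = study1_panel
        test = matrix.select(session=2)
        pooled = gwet_ac1(test)
        per_aspect = [gwet_ac1(test, aspect=a) for a in test.aspects]
        w = np.array([r.n_items for r in per_aspect], dtype=float)
        p_a = np.average([r.p_a for r in per_aspect], weights=w)
        p_e = np.average([r.p_e for r in per_aspect], weights=w)
        assert pooled.p_a == pytest.approx(p_a, abs=1e-12)
        assert pooled.p_e == pytest.approx(p_e, abs=1e-12)
        assert pooled.ac1 == pytest.approx((p_a - p_e) / (1 - p_e), abs=1e-12)

    def test_single_rated_items_rejected(self):
        panel = make_matrix([("r1", "i1", "cracks", 1, "mild")])
        with pytest.raises(AnalysisError):
            gwet_ac1(panel, aspect="cracks")

    def test_monotone_in_rater_accuracy(self):
        """Parameter recovery: AC1 grows with rater accuracy, reaching 1."""
        prior = {"tooth_marks": {c: 0.25 for c in vocabulary("tooth_marks")}}
        means = []
        for acc in (0.4, 0.7, 1.0):
            vals = []
            for seed in range(8):
                _, m = simulate_panel(
                    PanelConfig(
                        n_images=30,
                        aspects=("tooth_marks",),
                        n_raters=8,
                        rater_accuracy=acc,
                        truth_prior=prior,
                        n_sessions=1,
                        seed=seed,
                    )
                )
                vals.append(gwet_ac1(m, aspect="tooth_marks").ac1)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[2] == 1.0


class TestLandisKoch:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.53, "moderate"),
            (0.52, "moderate"),
            (0.47, "moderate"),
            (0.46, "moderate"),
            (0.45, "moderate"),
            (0.40, "moderate"),
            (0.38, "fair"),
            (0.27, "fair"),
            (-0.2, "poor"),
            (0.0, "slight"),
            (0.1999, "slight"),
            (0.65, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_landis_koch(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(AnalysisError):
            interpret_landis_koch(1.5)


class TestIntraraterMatch:
    def _two_sessions(self, flip_items=()):
        rows1, rows2 = [], []
        for r in ("a", "b"):
            for i in range(6):
                cat = "mild" if i % 2 else "none"
                rows1.append((r, f"i{i}", "cracks", 1, cat))
                cat2 = ("severe" if (r, i) in flip_items else cat)
                rows2.append((r, f"i{i}", "cracks", 2, cat2))
        return make_matrix(rows1), make_matrix(rows2)

    def test_identical_sessions_match_perfectly(self):
        s1, s2 = self._two_sessions()
        res = intrarater_match(s1, s2)
        assert res.overall_mean == 1.0
        assert all(v == 1.0 for v in res.per_rater.values())
        assert all(v == 1.0 for v in res.per_aspect.values())

    def test_total_mismatch_is_zero(self):
        s1, s2 = self._two_sessions(flip_items={(r, i) for r in "ab" for i in range(6)})
        assert intrarater_match(s1, s2).overall_mean == 0.0

    def test_partial_flip_counts_exactly(self):
        s1, s2 = self._two_sessions(flip_items={("a", 0), ("a", 1), ("b", 3)})
        res = intrarater_match(s1, s2)
        assert res.per_rater["a"] == pytest.approx(4 / 6)
        assert res.per_rater["b"] == pytest.approx(5 / 6)
        assert res.overall_mean == pytest.approx((4 / 6 + 5 / 6) / 2)
        assert res.overall_sd == pytest.approx(np.std([4 / 6, 5 / 6], ddof=1))

    def test_rater_without_overlap_omitted_with_warning(self):
        s1, s2 = self._two_sessions()
        extra = make_matrix([("zz", "i9", "cracks", 1, "none")])
        import pandas as pd

        from diagskill.model import ResponseMatrix

        s1x = ResponseMatrix.from_frame(pd.concat([s1.df, extra.df]))
        with pytest.warns(UserWarning, match="zz"):
            res = intrarater_match(s1x, s2)
        assert "zz" not in res.per_rater

    def test_simulated_consistency_recovered(self):
        """Binomial oracle: with session consistency 0.7 the observed mean
        match stays within 3 binomial SEs of 0.7."""
        matches = []
        n_pairs = 0
        for seed in range(5):
            _, m = simulate_panel(
                PanelConfig(n_raters=5, session_consistency=0.7, seed=seed)
            )
            res = intrarater_match_sessions(m)
            matches.append(res.overall_mean)
            n_pairs += 5 * 80
        se = np.sqrt(0.7 * 0.3 / n_pairs)
        assert abs(np.mean(matches) - 0.7) <= 3 * se
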