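"""Synthetic rater panels and cohorts.

No public dataset of per-rater diagnoses exists for this kind of assessment,
so every analysis stage is exercised on simulated data with the statistical
structure the methods assume.

A panel draws, for each item (one image x aspect question), a latent true
category; each rater reports the truth with their personal accuracy and
otherwise a wrong category from a confusion kernel (uniform over the wrong
categories by default, or "adjacent" with geometric decay along the ordered
vocabulary for ordinal aspects).

The second session is coupled to the first so that ``session_consistency``
is exactly the expected test-retest match rate while the rater's marginal
response distribution is unchanged: with probability
``lambda = (c - kappa) / (1 - kappa)`` the session-1 response is repeated,
otherwise a fresh draw is taken from the same rater model (``kappa`` is the
coincidence probability of two independent draws, so total match
probability is ``lambda + (1 - lambda) * kappa = c``).  When the target
``c`` lies below ``kappa`` a fresh draw alone would already agree too
often, so forced-different redraws are mixed in instead; a rater whose
response is deterministic (accuracy 1) always repeats.

Defaults mirror a 10-image, 8-aspect, 15-rater study: rater accuracy 0.62
(specialists averaged ~62/100 points) and session consistency 0.66 (the
observed mean test-retest match).  Everything is driven by a single integer
seed; identical configs produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import AnswerKey, KeyEntry, ResponseMatrix
from .vocab import ASPECT_NAMES, substantive_categories, vocabulary


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a simulated rater panel."""

    n_images: int = 10
    aspects: tuple[str, ...] = ASPECT_NAMES
    n_raters: int = 15
    rater_accuracy: float | Sequence[float] = 0.62
    truth_prior: Mapping[str, Mapping[str, float]] | None = None
    confusion: str = "uniform"  # or "adjacent"
    adjacency_decay: float = 0.5
    session_consistency: float = 0.66
    n_sessions: int = 2
    seed: int = 0

    def accuracies(self) -> np.ndarray:
        acc = self.rater_accuracy
        arr = (
            np.full(self.n_raters, float(acc))
            if np.isscalar(acc)
            else np.asarray(acc, dtype=float)
        )
        if arr.shape != (self.n_raters,):
            raise ConfigError(
                f"rater_accuracy must be scalar or length {self.n_raters}"
            )
        return arr

    def validate(self) -> None:
        if self.n_images < 1 or self.n_raters < 1:
            raise ConfigError("n_images and n_raters must be positive")
        if self.n_sessions not in (1, 2):
            raise ConfigError("n_sessions must be 1 or 2")
        unknown = set(self.aspects) - set(ASPECT_NAMES)
        if unknown:
            raise ConfigError(f"unknown aspects: {sorted(unknown)}")
        arr = self.accuracies()
        if ((arr < 0) | (arr > 1)).any():
            raise ConfigError("rater accuracies must lie in [0, 1]")
        if not 0.0 <= self.session_consistency <= 1.0:
            raise ConfigError("session_consistency must lie in [0, 1]")
        if self.confusion not in ("uniform", "adjacent"):
            raise ConfigError(f"unknown confusion kernel {self.confusion!r}")
        if not 0.0 < self.adjacency_decay <= 1.0:
            raise ConfigError("adjacency_decay must lie in (0, 1]")
        if self.truth_prior is not None:
            for aspect, prior in self.truth_prior.items():
                vocab = set(vocabulary(aspect))
                outside = set(prior) - vocab
                if outside:
                    raise ConfigError(
                        f"truth_prior for {aspect} names unknown categories {sorted(outside)}"
                    )
                total = float(sum(prior.values()))
                if abs(total - 1.0) > 1e-9 or any(p < 0 for p in prior.values()):
                    raise ConfigError(
                        f"truth_prior for {aspect} must be a probability distribution"
                    )


def _truth_prior_vector(config: PanelConfig, aspect: str) -> np.ndarray:
    vocab = vocabulary(aspect)
    if config.truth_prior is not None and aspect in config.truth_prior:
        prior = config.truth_prior[aspect]
        return np.array([prior.get(c, 0.0) for c in vocab], dtype=float)
    # default: uniform over substantive findings; "cannot assess" options are
    # answers raters may give, not states of the underlying tongue
    vec = np.array(
        [1.0 if c in substantive_categories(aspect) else 0.0 for c in vocab]
    )
    return vec / vec.sum()


def _confusion_weights(config: PanelConfig, aspect: str, truth_idx: int) -> np.ndarray:
    """Distribution over the wrong categories given the true one."""
    vocab = vocabulary(aspect)
    Q = len(vocab)
    if config.confusion == "uniform":
        w = np.ones(Q)
    else:  # geometric decay with index distance along the ordered vocabulary
        dist = np.abs(np.arange(Q) - truth_idx)
        w = config.adjacency_decay ** np.maximum(dist - 1, 0)
    w[truth_idx] = 0.0
    return w / w.sum()


def _draw_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of a rows x Q probability matrix."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def _second_session(
    rng: np.random.Generator, P: np.ndarray, s1: np.ndarray, c: float
) -> np.ndarray:
    """Couple a second draw to *s1* so that P(match) == *c* per rater.

    *P* is the raters x Q conditional response matrix.  The coupling keeps
    each rater's marginal distribution whenever ``c >= kappa`` (the
    independent-coincidence probability); below that, forced-different
    redraws are mixed in to thin the agreement down to ``c``.
    """
    n = P.shape[0]
    kappa = (P**2).sum(axis=1)
    u = rng.random(n)
    s2 = _draw_rows(rng, P)  # fresh independent draw for every rater

    deterministic = kappa >= 1.0 - 1e-12
    s2[deterministic] = s1[deterministic]

    hi = ~deterministic & (c >= kappa)
    if hi.any():
        lam = (c - kappa[hi]) / (1.0 - kappa[hi])
        repeat = np.zeros(n, dtype=bool)
        repeat[hi] = u[hi] < lam
        s2[repeat] = s1[repeat]

    lo = ~deterministic & (c < kappa)
    if lo.any():
        force = lo & (u < 1.0 - c / kappa)
        P2 = P.copy()
        P2[np.arange(n), s1] = 0.0
        mass = P2.sum(axis=1)
        force &= mass > 0
        if force.any():
            s2[force] = _draw_rows(rng, P2[force] / mass[force, None])
    return s2


def simulate_panel(config: PanelConfig) -> tuple[AnswerKey, ResponseMatrix]:
    """Generate a latent truth key and the panel's (1- or 2-session) responses."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    accuracies = config.accuracies()
    rater_ids = [f"r{i + 1:02d}" for i in range(config.n_raters)]

    key_entries: dict[str, KeyEntry] = {}
    rows: list[tuple[str, str, str, int, str]] = []
    for aspect in config.aspects:
        vocab = vocabulary(aspect)
        Q = len(vocab)
        prior = _truth_prior_vector(config, aspect)
        truth_idx = _draw_rows(rng, np.tile(prior, (config.n_images, 1)))
        for img in range(config.n_images):
            item_id = f"img{img + 1:02d}_{aspect}"
            t = int(truth_idx[img])
            key_entries[item_id] = KeyEntry(
                aspect=aspect,
                accepted=frozenset({vocab[t]}),
                provenance="simulated truth",
            )
            wrong = _confusion_weights(config, aspect, t)
            # rater x category conditional response distribution given truth
            P = np.outer(1.0 - accuracies, wrong)
            P[:, t] += accuracies
            s1 = _draw_rows(rng, P)
            for r, rid in enumerate(rater_ids):
                rows.append((rid, item_id, aspect, 1, vocab[s1[r]]))
            if config.n_sessions == 2:
                s2 = _second_session(rng, P, s1, config.session_consistency)
                for r, rid in enumerate(rater_ids):
                    rows.append((rid, item_id, aspect, 2, vocab[s2[r]]))

    df = pd.DataFrame(
        rows, columns=["rater_id", "item_id", "aspect", "session", "response"]
    )
    return AnswerKey(key_entries), ResponseMatrix.from_frame(df)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated examinee cohort (focal-item study)."""

    n_subjects: int = 107
    focal_correct_prob: float = 87 / 107
    score_mean_correct: float = 85.3
    score_sd_correct: float = 8.4
    score_mean_incorrect: float = 75.8
    score_sd_incorrect: float = 11.8
    covariate_priors: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "sex": {"male": 59 / 107, "female": 48 / 107},
            "age_band": {
                "20-29": 1 / 107,
                "30-39": 29 / 107,
                "40-49": 30 / 107,
                "50-59": 30 / 107,
                "60+": 17 / 107,
            },
            "lecture_attendance": {"yes": 47 / 107, "no": 60 / 107},
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        if not 0.0 <= self.focal_correct_prob <= 1.0:
            raise ConfigError("focal_correct_prob must lie in [0, 1]")
        if self.score_sd_correct < 0 or self.score_sd_incorrect < 0:
            raise ConfigError("score sds must be non-negative")
        for name, prior in self.covariate_priors.items():
            total = float(sum(prior.values()))
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in prior.values()):
                raise ConfigError(f"covariate prior {name!r} must sum to 1")


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort table: focal-item correctness, covariates, total score.

    Correctness is Bernoulli(``focal_correct_prob``); the total score is
    normal with group-conditional mean/sd, clipped to [0, 100]; covariates
    are drawn independently from their priors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    correct = rng.random(n) < config.focal_correct_prob
    means = np.where(correct, config.score_mean_correct, config.score_mean_incorrect)
    sds = np.where(correct, config.score_sd_correct, config.score_sd_incorrect)
    scores = np.clip(rng.normal(means, sds), 0.0, 100.0)
    data: dict[str, object] = {
        "examinee_id": [f"s{i + 1:03d}" for i in range(n)],
        "group": np.where(correct, "correct", "incorrect"),
    }
    for name, prior in config.covariate_priors.items():
        levels = list(prior)
        probs = np.array([prior[lv] for lv in levels], dtype=float)
        idx = _draw_rows(rng, np.tile(probs, (n, 1)))
        data[name] = [levels[i] for i in idx]
    data["total_score"] = scores
    return pd.DataFrame(data)
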