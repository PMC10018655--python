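"""Simulated multi-reader, paired-condition ordinal image-quality ratings.

Observer behaviour is modelled with a cumulative-threshold (ordered
categories) latent-variable model: the perceived quality of an image is

    latent = condition_mean + case_effect + reader_effect + noise

with condition_mean 0 for the reference condition and ``delta`` for the test
condition, Gaussian case/reader effects shared between the two conditions of
a pair, and iid Gaussian noise per individual reading.  The latent value is
cut into ordinal categories by fixed ascending thresholds; the category is
``1 + number of thresholds below the latent value`` (higher category =
better perceived quality).

With zero case/reader effects the model has a closed-form ground truth: the
probability that a test reading's latent value exceeds a reference reading's
is Phi(delta / (sigma_noise * sqrt(2))), which the rank-based AUC analysis
should recover — the basis of the parameter-recovery tests.

Raw ratings are stored in the questionnaire's own coding: five-step
criterion scales code 1 = "confident the criterion is fulfilled" (best)
through 5 = "confident not fulfilled" (worst), while three-step
acceptability scales code 1 = "unacceptable" through 3 = "fully acceptable"
(best).  The VGC analysis re-orients both so that larger always means
better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scipy.stats import norm

__all__ = [
    "Question", "RatingDesign", "LatentRatingModel", "RatingSet",
    "generate_ratings", "default_rating_design", "true_auc",
    "RATING_COLUMNS",
]

RATING_COLUMNS = ["case_id", "reader_id", "question_id", "condition", "rating", "scale_size"]

#: base latent cut-points per scale size, symmetric about 0.  The model
#: centres them midway between the two condition means (a delta/2 shift) so
#: category usage is balanced across conditions; the 5-step spacing keeps
#: the discretisation bias of the tie-corrected rank AUC near its minimum,
#: which is what makes closed-form parameter recovery possible.
BASE_THRESHOLDS = {
    3: (-0.5, 0.5),
    5: (-1.05, -0.35, 0.35, 1.05),
}


@dataclass(frozen=True)
class Question:
    id: str
    scale_size: int

    def __post_init__(self) -> None:
        if self.scale_size not in (3, 5):
            raise ValueError("scale_size must be 3 or 5")


@dataclass
class RatingDesign:
    """Paired two-condition observer-study layout."""

    n_cases: int = 25
    n_readers: int = 5
    questions: Sequence[Question] = field(default_factory=list)
    conditions: tuple = ("reference", "test")

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_readers < 1:
            raise ValueError("n_cases and n_readers must be at least 1")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError("exactly two distinct conditions are required")
        if not self.questions:
            raise ValueError("at least one question is required")


def default_rating_design(conditions: tuple = ("reference", "test")) -> RatingDesign:
    """Study layout used throughout: 25 cases, 5 readers, 10 questions —
    Q1-Q6 on five-step criterion scales, Q7-Q10 on three-step acceptability
    scales."""
    questions = [Question(f"Q{i}", 5) for i in range(1, 7)]
    questions += [Question(f"Q{i}", 3) for i in range(7, 11)]
    return RatingDesign(n_cases=25, n_readers=5, questions=questions,
                        conditions=conditions)


@dataclass
class LatentRatingModel:
    """Cumulative-threshold observer model.

    ``thresholds`` maps scale size to ascending latent cut-points; if left
    unset they default to BASE_THRESHOLDS shifted by delta/2, i.e. centred
    midway between the reference and test condition means.
    """

    delta: float = 0.0
    sigma_case: float = 0.5
    sigma_reader: float = 0.3
    sigma_noise: float = 1.0
    thresholds: dict = None

    def __post_init__(self) -> None:
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if self.sigma_case < 0 or self.sigma_reader < 0:
            raise ValueError("effect SDs must be non-negative")
        if self.thresholds is None:
            self.thresholds = {
                scale: tuple(c + self.delta / 2.0 for c in cuts)
                for scale, cuts in BASE_THRESHOLDS.items()
            }
        for scale, cuts in self.thresholds.items():
            if len(cuts) != scale - 1:
                raise ValueError(f"scale {scale} needs {scale - 1} thresholds")
            if np.any(np.diff(cuts) <= 0):
                raise ValueError("thresholds must be strictly ascending")


def true_auc(model: LatentRatingModel) -> float:
    """Closed-form latent AUC: P(test latent > reference latent) for a pair
    sharing case and reader effects (which cancel in the difference)."""
    return float(norm.cdf(model.delta / (model.sigma_noise * np.sqrt(2.0))))


@dataclass
class RatingSet:
    """Paired ordinal ratings over case x reader x question x condition.

    ``conditions`` is the ordered (reference, test) pair; ``data`` holds one
    row per reading with columns RATING_COLUMNS.
    """

    data: pd.DataFrame
    conditions: tuple

    def __post_init__(self) -> None:
        missing = [c for c in RATING_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"rating table missing columns {missing}")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        bad = self.data[(self.data["rating"] < 1)
                        | (self.data["rating"] > self.data["scale_size"])]
        if len(bad):
            raise ValueError(f"{len(bad)} ratings outside 1..scale_size "
                             f"(first at index {bad.index[0]})")
        unknown = set(self.data["condition"].unique()) - set(self.conditions)
        if unknown:
            raise ValueError(f"unknown conditions in table: {sorted(unknown)}")
        dup = self.data.duplicated(subset=["case_id", "reader_id", "question_id", "condition"])
        if dup.any():
            raise ValueError(f"duplicate (case, reader, question, condition) rows "
                             f"(first at index {self.data.index[dup][0]})")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def test(self) -> str:
        return self.conditions[1]

    @property
    def question_ids(self) -> list:
        return sorted(self.data["question_id"].unique())

    def check_paired(self) -> None:
        """Raise if any (case, reader, question) lacks one of the two conditions."""
        counts = self.data.pivot_table(index=["case_id", "reader_id", "question_id"],
                                       columns="condition", values="rating",
                                       aggfunc="size", fill_value=0)
        for cond in self.conditions:
            if cond not in counts.columns:
                raise ValueError(f"condition {cond!r} absent from the rating set")
            missing = counts.index[counts[cond] == 0]
            if len(missing):
                raise ValueError(f"missing {cond!r} rating for (case, reader, question) "
                                 f"= {tuple(missing[0])}")


def _categorise(latent: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    # category = 1 + number of thresholds strictly below the latent value
    return 1 + np.searchsorted(np.asarray(cuts), latent, side="left")


def generate_ratings(design: RatingDesign, model: LatentRatingModel, seed: int) -> RatingSet:
    """Simulate a complete paired rating study.

    Case and reader effects are drawn once per study and shared across
    questions and conditions; reading noise is independent per
    (case, reader, question, condition).
    """
    rng = np.random.default_rng(seed)
    nc, nr = design.n_cases, design.n_readers
    case_eff = model.sigma_case * rng.standard_normal(nc)
    reader_eff = model.sigma_reader * rng.standard_normal(nr)
    ref, test = design.conditions

    rows = []
    for q in design.questions:
        cuts = model.thresholds[q.scale_size]
        for cond, mean in ((ref, 0.0), (test, model.delta)):
            noise = model.sigma_noise * rng.standard_normal((nc, nr))
            latent = mean + case_eff[:, None] + reader_eff[None, :] + noise
            cat = _categorise(latent, cuts)
            if q.scale_size == 5:
                raw = 6 - cat  # five-step scales code 1 = best
            else:
                raw = cat      # three-step scales code 3 = best
            for ci in range(nc):
                for ri in range(nr):
                    rows.append((f"case{ci + 1:03d}", f"reader{ri + 1}", q.id,
                                 cond, int(raw[ci, ri]), q.scale_size))
    data = pd.DataFrame(rows, columns=RATING_COLUMNS)
    return RatingSet(data=data, conditions=design.conditions)
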