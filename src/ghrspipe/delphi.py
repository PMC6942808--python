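"""Delphi consensus item screening.

A panel of experts scores each candidate symptom on a 5-point Likert scale
(0 = unimportant ... 4 = very important).  Items are reduced by three
consensus statistics computed per item:

* mean expert score,
* full-mark rate (percentage of experts awarding the maximum score 4),
* variable coefficient (coefficient of variation: sd / mean).

An item is deleted when it fails any one of three cutoffs derived from the
across-item distribution of those statistics (mean - sd for the two "higher
is better" statistics, mean + sd for the coefficient of variation).
Cronbach's alpha summarises the internal consistency of the panel's scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpertScoreMatrix",
    "ThresholdSet",
    "ScreeningResult",
    "ReliabilityResult",
    "item_statistics",
    "deletion_thresholds",
    "apply_deletion_rules",
    "cronbach_alpha",
]

MAX_SCORE = 4

#: deletion rule identifiers, in the order the rules are stated
RULE_LOW_MEAN = "low_mean"
RULE_LOW_FULLMARK = "low_fullmark"
RULE_HIGH_CV = "high_cv"


@dataclass
class ExpertScoreMatrix:
    """Raters x items matrix of ordinal Likert scores in {0..4}."""

    round_id: int
    item_labels: list[str]
    expert_ids: list[str]
    scores: np.ndarray  # shape (n_experts, n_items), integer

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-d matrix (experts x items)")
        n_experts, n_items = self.scores.shape
        if n_experts < 2 or n_items < 2:
            raise ValueError("need at least 2 experts and 2 items")
        if len(self.expert_ids) != n_experts or len(self.item_labels) != n_items:
            raise ValueError("label lengths do not match the score matrix")
        if len(set(self.item_labels)) != n_items:
            raise ValueError("item labels must be unique")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError("scores must be integers")
            self.scores = self.scores.astype(int)
        if self.scores.min() < 0 or self.scores.max() > MAX_SCORE:
            raise ValueError(f"scores must lie in [0, {MAX_SCORE}]")

    @property
    def n_experts(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.expert_ids, columns=self.item_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="expert_id")

    @classmethod
    def from_csv(cls, path, round_id: int = 0) -> "ExpertScoreMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            round_id=round_id,
            item_labels=list(frame.columns),
            expert_ids=[str(i) for i in frame.index],
            scores=frame.to_numpy(),
        )


@dataclass(frozen=True)
class ThresholdSet:
    """The three deletion cutoffs derived from the across-item distribution."""

    score_min: float  # mean(mean_score) - sd(mean_score)
    cv_max: float  # mean(CV) + sd(CV)
    fullmark_min: float  # mean(full_mark_rate) - sd(full_mark_rate)


@dataclass
class ScreeningResult:
    retained: list[str]
    #: deleted item -> set of rule names it triggered
    deleted: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_deleted(self) -> int:
        return len(self.deleted)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": it, "status": "retained", "rules": ""} for it in self.retained]
        rows += [
            {"item": it, "status": "deleted", "rules": "|".join(sorted(rules))}
            for it, rules in self.deleted.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    k: int
    item_variances: np.ndarray
    total_variance: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.alpha)


def item_statistics(matrix: ExpertScoreMatrix) -> pd.DataFrame:
    """Per-item mean score, coefficient of variation, and full-mark rate (%).

    An item whose mean score is zero has an undefined coefficient of
    variation; it is reported as NaN rather than raising, and the deletion
    rules handle it explicitly (a zero mean always fails the mean-score rule
    whenever the cutoff is positive).
    """
    scores = matrix.scores.astype(float)
    means = scores.mean(axis=0)
    sds = scores.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / np.where(means > 0, means, 1.0), np.nan)
    full = (matrix.scores == MAX_SCORE).mean(axis=0) * 100.0
    return pd.DataFrame(
        {
            "mean_score": means,
            "variable_coefficient": cvs,
            "full_mark_rate": full,
        },
        index=pd.Index(matrix.item_labels, name="item"),
    )


def deletion_thresholds(stats: pd.DataFrame) -> ThresholdSet:
    """Cutoffs from the across-item mean and sample sd of each statistic.

    Items with an undefined (NaN) coefficient of variation are excluded from
    the CV mean/sd.  At least two items are required, otherwise the sd is
    undefined.
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 items to derive thresholds")
    ms = stats["mean_score"].to_numpy(float)
    fm = stats["full_mark_rate"].to_numpy(float)
    cv = stats["variable_coefficient"].to_numpy(float)
    cv = cv[~np.isnan(cv)]
    if len(cv) < 2:
        raise ValueError("need at least 2 items with a defined CV")
    return ThresholdSet(
        score_min=ms.mean() - ms.std(ddof=1),
        cv_max=cv.mean() + cv.std(ddof=1),
        fullmark_min=fm.mean() - fm.std(ddof=1),
    )


def apply_deletion_rules(stats: pd.DataFrame, thresholds: ThresholdSet) -> ScreeningResult:
    """Delete every item that fails at least one rule (strict inequalities).

    Rules: mean score strictly below ``score_min``; full-mark rate strictly
    below ``fullmark_min``; coefficient of variation strictly above
    ``cv_max``.  A NaN CV never triggers the CV rule.
    """
    required = {"mean_score", "variable_coefficient", "full_mark_rate"}
    if not required.issubset(stats.columns):
        raise ValueError(f"stats table missing columns: {required - set(stats.columns)}")
    if stats[["mean_score", "full_mark_rate"]].isna().any().any():
        raise ValueError("mean_score / full_mark_rate must not contain missing values")

    retained: list[str] = []
    deleted: dict[str, set[str]] = {}
    for item, row in stats.iterrows():
        rules: set[str] = set()
        if row["mean_score"] < thresholds.score_min:
            rules.add(RULE_LOW_MEAN)
        if row["full_mark_rate"] < thresholds.fullmark_min:
            rules.add(RULE_LOW_FULLMARK)
        cv = row["variable_coefficient"]
        if not math.isnan(cv) and cv > thresholds.cv_max:
            rules.add(RULE_HIGH_CV)
        if rules:
            deleted[str(item)] = rules
        else:
            retained.append(str(item))
    return ScreeningResult(retained=retained, deleted=deleted)


def screen_items(matrix: ExpertScoreMatrix) -> tuple[pd.DataFrame, ThresholdSet, ScreeningResult]:
    """Convenience chain: statistics -> thresholds -> deletion rules."""
    stats = item_statistics(matrix)
    thresholds = deletion_thresholds(stats)
    return stats, thresholds, apply_deletion_rules(stats, thresholds)


def cronbach_alpha(matrix: ExpertScoreMatrix) -> ReliabilityResult:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(total)).

    Variances use the sample (n-1) denominator over raters.  If the rater
    total scores have zero variance, alpha is undefined and reported as NaN
    (``ReliabilityResult.defined`` is False).
    """
    scores = matrix.scores.astype(float)
    k = matrix.n_items
    item_var = scores.var(axis=0, ddof=1)
    total_var = scores.sum(axis=1).var(ddof=1)
    if total_var == 0:
        alpha = float("nan")
    else:
        alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(alpha=alpha, k=k, item_variances=item_var, total_variance=total_var)
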