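"""Cohort description: 2x2 cross-tabulation and Pearson chi-square tests.

The group comparisons are uncorrected Pearson chi-square tests on 2x2
tables (diagnosis x covariate); Yates continuity correction is available
behind a flag but off by default, matching how the reference values were
computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ContingencyTable", "ChiSquareResult", "crosstab", "pearson_chi_square"]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # 2x2 integer counts
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("grand total must be at least 1")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Percentages within each row (i.e. within diagnosis group)."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        return 100.0 * self.counts / row_sums

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def crosstab(dataset, covariate: str) -> ContingencyTable:
    """Tally diagnosis label against a two-level covariate.

    ``dataset`` is a :class:`~ghrspipe.simulate.ClinicalDataset` (or any
    object with a ``frame`` DataFrame holding ``label`` and the covariate).
    Rows are (positive, negative); columns are the two covariate levels in
    sorted order.
    """
    frame = dataset.frame if hasattr(dataset, "frame") else dataset
    if len(frame) == 0:
        raise ValueError("dataset is empty")
    if covariate not in frame.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    levels = sorted(frame[covariate].unique())
    if len(levels) != 2:
        raise ValueError(f"covariate {covariate!r} has {len(levels)} observed levels, need 2")
    counts = np.zeros((2, 2), dtype=int)
    for i, lab in enumerate(("positive", "negative")):
        sub = frame[frame["label"] == lab]
        for j, lev in enumerate(levels):
            counts[i, j] = int((sub[covariate] == lev).sum())
    return ContingencyTable(counts=counts, row_labels=("positive", "negative"),
                            col_labels=(str(levels[0]), str(levels[1])))


def pearson_chi_square(table: ContingencyTable, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction by default."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin; chi-square undefined")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=correction)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))
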