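"""Statistical routines: Welch t tests with Bonferroni capping, Pearson
R-squared, and the two-way mixed absolute-agreement ICC.

The t test is the two-sided independent-sample (Welch) form; reported
p-values are multiplied by the number of comparisons and capped at 1.0
(Bonferroni), matching summary tables that print p = 1.000. ICC is the
single-measures absolute-agreement form ICC(A,1), computed from the
two-way mean squares; the average-measures form ICC(A,k) is available
behind a flag.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "t_test_independent",
    "pearson_r2",
    "RaterTable",
    "icc_absolute_agreement",
    "icc_interpretation",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


def _check_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"{name} needs >= 2 values")
    if np.ptp(x) == 0:
        raise ValueError(f"{name} has zero variance")
    return x


def t_test_independent(x, y, n_comparisons: int = 1) -> float:
    """Two-sided Welch t test, Bonferroni-multiplied and capped at 1.0."""
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    p = sps.ttest_ind(x, y, equal_var=False).pvalue
    return float(min(1.0, p * n_comparisons))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation coefficient, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


@dataclasses.dataclass
class RaterTable:
    """Measurements indexed by (subject, rater, occasion), one metric.

    ``matrix`` extracts the complete subjects x raters table required by
    the ICC (raising if any cell is missing).
    """

    data: pd.DataFrame  # columns: subject, rater, occasion, value
    metric: str = ""

    def __post_init__(self):
        required = {"subject", "rater", "occasion", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"RaterTable missing columns {sorted(missing)}")

    @classmethod
    def from_matrix(cls, matrix, metric: str = "") -> "RaterTable":
        matrix = np.asarray(matrix, dtype=float)
        rows = [
            {"subject": i, "rater": j, "occasion": 1, "value": matrix[i, j]}
            for i in range(matrix.shape[0])
            for j in range(matrix.shape[1])
        ]
        return cls(pd.DataFrame(rows), metric=metric)

    def matrix(self, occasion: int | None = 1) -> np.ndarray:
        df = self.data
        if occasion is not None:
            df = df[df["occasion"] == occasion]
        pivot = df.pivot_table(index="subject", columns="rater", values="value")
        if pivot.isna().any().any():
            raise ValueError("incomplete crossed design: missing subject x rater cells")
        return pivot.to_numpy(dtype=float)


def icc_absolute_agreement(table: RaterTable | np.ndarray,
                           form: str = "single") -> float:
    """Two-way absolute-agreement ICC from the subjects x raters table.

    form="single" gives ICC(A,1) = (MSR - MSE) /
    (MSR + (k-1) MSE + k (MSC - MSE) / n); form="average" gives ICC(A,k).
    """
    if isinstance(table, RaterTable):
        m = table.matrix()
    else:
        m = np.asarray(table, dtype=float)
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "average":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError("form must be 'single' or 'average'")
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def icc_interpretation(icc: float) -> str:
    """Conventional reliability bands for an ICC value."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"
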