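"""Agreement statistics for paired measurement methods.

Implements the Bland-Altman workflow used to compare two ways of
measuring the same eyes (e.g. individual vs. constant conversion factor,
or optic-disc- vs. macula-centered views): the mean difference
``md = mean(x - y)``, its sample SD, limits of agreement ``md +/-
1.96 SD``, a one-sample t test of the differences against zero
(systematic bias), and an OLS regression of the differences on the
pairwise means (proportional bias).  Paired location comparisons choose
between the paired t test and the Wilcoxon signed-rank test by a
normality rule on the differences, and the multiple-comparison
threshold is plain Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementSummary",
    "PairedTestResult",
    "bland_altman",
    "paired_compare",
    "bonferroni_threshold",
    "correlation_table",
]


class AgreementError(ValueError):
    pass


@dataclass
class PairedSeries:
    """Two aligned measurement series of the same images."""

    labels: Sequence
    x: np.ndarray  # method 1
    y: np.ndarray  # method 2

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.labels) == self.x.size == self.y.size):
            raise AgreementError("labels, x and y must be aligned")
        if self.x.size < 3:
            raise AgreementError("need at least three pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y

    def swapped(self) -> "PairedSeries":
        return PairedSeries(self.labels, self.y.copy(), self.x.copy())


@dataclass
class AgreementSummary:
    mean_diff: float
    sd_diff: float
    upper_loa: float
    lower_loa: float
    bias_p: float
    prop_bias_slope: float
    prop_bias_p: float
    n: int
    degenerate: bool = False


@dataclass
class PairedTestResult:
    p_value: float
    test: str                  # "paired-t" | "wilcoxon"
    statistic: float
    all_zero: bool = False


def bland_altman(s: PairedSeries) -> AgreementSummary:
    """Bland-Altman agreement of ``s.x`` against ``s.y``.

    ``sd_diff`` is the sample (n-1) estimator; limits of agreement are
    ``md +/- 1.96 sd``.  With zero variance of the differences the bias
    tests are undefined and the summary is flagged degenerate.
    """
    d = s.differences
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    upper, lower = md + 1.96 * sd, md - 1.96 * sd
    if sd == 0:
        return AgreementSummary(md, 0.0, md, md, float("nan"),
                                0.0, float("nan"), d.size, degenerate=True)
    bias_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    mean_xy = (s.x + s.y) / 2.0
    if np.ptp(mean_xy) == 0:
        slope, slope_p = 0.0, float("nan")
        degenerate = True
    else:
        reg = stats.linregress(mean_xy, d)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
        degenerate = False
    return AgreementSummary(md, sd, upper, lower, bias_p, slope, slope_p,
                            d.size, degenerate=degenerate)


def paired_compare(s: PairedSeries, normality_alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired location test with a normality-driven branch.

    Shapiro-Wilk on the differences at ``normality_alpha`` selects the
    paired t test (normal) or the Wilcoxon signed-rank test (skewed).
    All-zero differences return p = 1 by convention, flagged.
    """
    d = s.differences
    if np.all(d == 0):
        return PairedTestResult(1.0, "paired-t", 0.0, all_zero=True)
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= normality_alpha:
        res = stats.ttest_rel(s.x, s.y)
        return PairedTestResult(float(res.pvalue), "paired-t", float(res.statistic))
    res = stats.wilcoxon(s.x, s.y, zero_method="wilcox", alternative="two-sided")
    return PairedTestResult(float(res.pvalue), "wilcoxon", float(res.statistic))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold ``alpha / m``."""
    if not (0 < alpha < 1):
        raise AgreementError("alpha must be in (0, 1)")
    if m < 1:
        raise AgreementError("m must be >= 1")
    return alpha / m


def correlation_table(
    rvgc_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlations of every (clinical, RVGC) column pair.

    Missing values are handled pairwise-complete; cells with fewer than
    ``min_pairs`` complete pairs or a constant column are reported with
    NaN statistics.  Returns a tidy frame (clinical, rvgc, rho, p, n).
    """
    rows = []
    for cvar in clinical_table.columns:
        for rvar in rvgc_table.columns:
            a = pd.to_numeric(clinical_table[cvar], errors="coerce")
            b = pd.to_numeric(rvgc_table[rvar], errors="coerce")
            ok = a.notna() & b.notna()
            n = int(ok.sum())
            if n < min_pairs or a[ok].nunique() < 2 or b[ok].nunique() < 2:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.pearsonr(a[ok], b[ok])
            rows.append({"clinical": cvar, "rvgc": rvar,
                         "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows)
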