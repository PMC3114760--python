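"""Test-selection protocol for pairwise sample comparisons.

Distribution comparisons follow a fixed gate: normality of each sample
is checked (Shapiro-Wilk) and recorded; a two-sample Kolmogorov-Smirnov
test then probes whether the samples share a distribution shape.  If KS
rejects, the KS result itself is reported; otherwise the Wilcoxon
rank-sum test is run and reported.  All tests are two-tailed.  The gate
uses KS both as the shape check and as the reported test when it
rejects; this circularity is inherited from the protocol being encoded
and is flagged here rather than repaired.

Library implementations (scipy) are used throughout; this module only
encodes the selection logic, the trace, and a Pearson correlation
helper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestReport", "select_and_test", "pearson_with_p"]


@dataclass
class TestReport:
    """Chosen test, its result, and the full gate trace."""

    test: str            # "KS" or "Wilcoxon"
    statistic: float
    p: float
    shapiro_p_a: float
    shapiro_p_b: float
    ks_statistic: float
    ks_p: float


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return math.nan  # constant sample: normality test undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def select_and_test(sample_a, sample_b, alpha_gate: float = 0.05) -> TestReport:
    """Run the KS-gated two-sample comparison (two-tailed).

    Exact Wilcoxon null distribution is used for samples of <= 25
    without ties, the normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    sh_a, sh_b = _shapiro_p(a), _shapiro_p(b)
    ks = sps.ks_2samp(a, b, alternative="two-sided")
    if ks.pvalue < alpha_gate:
        return TestReport(test="KS", statistic=float(ks.statistic),
                          p=float(ks.pvalue), shapiro_p_a=sh_a, shapiro_p_b=sh_b,
                          ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue))
    ties = np.intersect1d(a, b).size > 0 or a.size != np.unique(a).size \
        or b.size != np.unique(b).size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not ties) else "asymptotic"
    mw = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestReport(test="Wilcoxon", statistic=float(mw.statistic),
                      p=float(min(1.0, mw.pvalue)), shapiro_p_a=sh_a,
                      shapiro_p_b=sh_b, ks_statistic=float(ks.statistic),
                      ks_p=float(ks.pvalue))


def pearson_with_p(x, y) -> tuple:
    """Pearson r with the two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance sample")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
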