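"""Fluctuation-assay mutation rates: Ma-Sandri-Sarkar MLE and CIs.

Mutant counts from parallel cultures follow the Luria-Delbruck
(Lea-Coulson) distribution with parameter m, the expected number of
mutational events per culture.  The pmf satisfies the Ma-Sandri-Sarkar
recursion

    p_0 = exp(-m),    p_k = (m/k) * sum_{i=0}^{k-1} p_i / (k - i + 1),

and m is estimated by maximising the product of per-culture
probabilities (golden-section search on log m; counts above a jackpot
ceiling are right-censored using the distribution's tail mass, since
plate counts saturate).  The phenotypic mutation rate is mu = m/Nt
(mutations per cell division, with Nt cells per culture); 95%
confidence limits use the Rosche-Foster approximation on ln m,

    sigma = 1.225 * m^(-0.315) / sqrt(C),    CI = exp(ln m +/- 1.96 sigma) / Nt.

Strain comparisons are two-sided Welch t-tests on replicate rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluctuationExperiment",
    "MutationRateEstimate",
    "ld_pmf",
    "log_likelihood",
    "estimate_m",
    "mutation_rate",
    "rate_ci",
    "estimate_experiment",
    "compare_strains",
]

DEFAULT_CEILING = 150


@dataclass
class FluctuationExperiment:
    """Per-culture mutant colony counts and total cells per culture."""

    counts: np.ndarray
    Nt: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.size < 1:
            raise ValueError("need >= 1 culture")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be non-negative integers")
            self.counts = as_int
        if bool((self.counts < 0).any()):
            raise ValueError("counts must be non-negative integers")
        if self.Nt < 1:
            raise ValueError("Nt must be >= 1")

    @property
    def C(self) -> int:
        return int(self.counts.size)


@dataclass
class MutationRateEstimate:
    m: float
    mu: float
    ci_lo: float
    ci_hi: float


def ld_pmf(m: float, max_k: int) -> np.ndarray:
    """Lea-Coulson probabilities p_0..p_max_k via the MSS recursion.

    The distribution is heavy-tailed (p_k ~ m/k^2), so the partial sum
    approaches 1 only like 1 - O(m/max_k).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    p = np.zeros(max_k + 1)
    p[0] = math.exp(-m)
    if m == 0 or max_k == 0:
        return p
    inv = 1.0 / (np.arange(max_k + 1, dtype=float) + 1.0)  # inv[j] = 1/(j+1)
    for k in range(1, max_k + 1):
        # sum_{i=0}^{k-1} p_i / (k - i + 1)
        p[k] = (m / k) * float(np.dot(p[:k], inv[1:k + 1][::-1]))
    return p


def log_likelihood(m: float, counts: np.ndarray, ceiling: int = DEFAULT_CEILING) -> float:
    """Log-likelihood of per-culture counts; counts >= ceiling are
    right-censored via the tail mass."""
    counts = np.asarray(counts)
    capped = np.minimum(counts, ceiling)
    kmax = int(capped.max(initial=0))
    if m == 0:
        return 0.0 if kmax == 0 else -math.inf
    p = ld_pmf(m, min(kmax, ceiling - 1) if kmax >= ceiling else kmax)
    ll = 0.0
    tail = None
    for c in capped:
        if c >= ceiling:
            if tail is None:
                full = ld_pmf(m, ceiling - 1)
                tail = max(1.0 - float(full.sum()), 1e-300)
            ll += math.log(tail)
        else:
            ll += math.log(max(float(p[c]), 1e-300))
    return ll


def estimate_m(experiment, ceiling: int = DEFAULT_CEILING,
               lo: float = 1e-6, hi: float = 50.0, tol: float = 1e-8) -> float:
    """Maximum-likelihood m via golden-section search on log m.

    Deterministic; returns the boundary MLE 0 when all counts are zero
    (the likelihood exp(-C m) is maximised at m = 0).
    """
    counts = experiment.counts if isinstance(experiment, FluctuationExperiment) \
        else FluctuationExperiment(np.asarray(experiment), Nt=1).counts
    if int(counts.max(initial=0)) == 0:
        return 0.0
    a, b = math.log(lo), math.log(hi)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = log_likelihood(math.exp(c), counts, ceiling)
    fd = log_likelihood(math.exp(d), counts, ceiling)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = log_likelihood(math.exp(c), counts, ceiling)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = log_likelihood(math.exp(d), counts, ceiling)
    return math.exp((a + b) / 2.0)


def mutation_rate(m: float, Nt: float) -> float:
    """mu = m / Nt, mutations per cell division."""
    if Nt <= 0:
        raise ValueError("Nt must be positive")
    return m / Nt


def rate_ci(m: float, C: int, Nt: float, z: float = 1.96) -> tuple:
    """Rosche-Foster 95% confidence limits on mu = m/Nt.

    For m = 0 a sentinel interval [0, upper] is returned, with the
    upper limit from P(all C cultures show zero mutants) = 0.025.
    """
    if Nt <= 0:
        raise ValueError("Nt must be positive")
    if C < 2:
        raise ValueError("need C >= 2 cultures")
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return 0.0, -math.log(0.025) / C / Nt
    sigma = 1.225 * m ** (-0.315) / math.sqrt(C)
    return (math.exp(math.log(m) - z * sigma) / Nt,
            math.exp(math.log(m) + z * sigma) / Nt)


def estimate_experiment(experiment: FluctuationExperiment,
                        ceiling: int = DEFAULT_CEILING) -> MutationRateEstimate:
    """MLE m, rate mu = m/Nt, and Rosche-Foster 95% CI for one experiment."""
    m = estimate_m(experiment, ceiling=ceiling)
    mu = mutation_rate(m, experiment.Nt)
    lo, hi = rate_ci(m, experiment.C, experiment.Nt)
    return MutationRateEstimate(m=m, mu=mu, ci_lo=lo, ci_hi=hi)


def compare_strains(rates_a, rates_b) -> tuple:
    """Two-sided Welch t-test on replicate mutation-rate estimates.

    Returns (t, p).  Identical replicate sets give (0.0, 1.0).
    """
    from scipy.stats import ttest_ind

    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicate estimates per strain")
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0 and a.mean() == b.mean()):
        return 0.0, 1.0
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
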