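"""Allelic-imbalance statistics.

The central model: at a heterozygous site, each sequenced tag (read pair)
independently supports one of the two alleles, so the allele-supporting
count among ``n`` tags is Binomial(n, pi). Balanced interaction, binding or
expression corresponds to pi = 0.5.

* :func:`binom_two_sided` — exact two-sided binomial test for one experiment.
* :func:`lrt_combined` — likelihood-ratio test pooling several experiments:

  ``LRT = 2 * sum_i [ n_iA*ln(pi1/pi0) + (n_i - n_iA)*ln((1-pi1)/(1-pi0)) ]``

  with ``pi1 = sum_i n_iA / sum_i n_i`` (the weighted proportion) and
  ``pi0 = 0.5`` under the null; the statistic is compared to chi-square with
  1 degree of freedom.
* :func:`odds_fold` — converts a proportion into the implied fold difference
  ``p / (1 - p)`` between alleles.
* paired / one-sample / Welch t-tests used for allele-specific expression and
  expression fold-change analyses, with an explicit degenerate
  (zero-variance) contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_TIE_REL_TOL = 1e-7  # relative tolerance for probability ties in the exact test


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    estimate: float
    df: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class ExperimentCounts:
    """Per-experiment totals ``n_i`` and allele-"A"-supporting counts ``n_iA``."""

    experiments: list[tuple[int, int]]
    pi0: float = 0.5

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("at least one experiment required")
        for i, (n, k) in enumerate(self.experiments):
            if n < 1:
                raise ValueError(f"experiment {i}: n_i must be >= 1, got {n}")
            if not 0 <= k <= n:
                raise ValueError(f"experiment {i}: n_iA={k} outside [0, {n}]")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError(f"pi0 must be in (0, 1), got {self.pi0}")

    @property
    def total(self) -> int:
        return sum(n for n, _ in self.experiments)

    @property
    def total_a(self) -> int:
        return sum(k for _, k in self.experiments)

    @property
    def pi1(self) -> float:
        """Weighted proportion across experiments, sum n_iA / sum n_i."""
        return self.total_a / self.total


def binom_two_sided(n: int, k: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test by the minimum-likelihood method.

    The p-value sums P(X = j) over all outcomes j whose point probability is
    at most P(X = k) * (1 + 1e-7) — the common exact-test convention.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    logpmf = stats.binom.logpmf(np.arange(n + 1), n, p0)
    cutoff = logpmf[k] + math.log1p(_TIE_REL_TOL)
    p = float(np.exp(logpmf[logpmf <= cutoff]).sum())
    p = min(1.0, p)
    return TestResult("binomial (two-sided, min-likelihood)", p, p, k / n)


def lrt_combined(data: ExperimentCounts) -> TestResult:
    """Likelihood-ratio test for allelic imbalance pooled over experiments.

    Because ``pi1`` is the pooled MLE, the statistic depends on the data only
    through the totals; per-experiment structure is retained in the input for
    bookkeeping. Uses the 0*ln(0) = 0 convention when ``pi1`` hits 0 or 1.
    """
    pi0, pi1 = data.pi0, data.pi1
    total, total_a = data.total, data.total_a

    def xlog(x: float, ratio: float) -> float:
        return 0.0 if x == 0 else x * math.log(ratio)

    stat = 0.0
    for n, k in data.experiments:
        stat += xlog(k, pi1 / pi0) if pi1 > 0 else 0.0
        stat += xlog(n - k, (1 - pi1) / (1 - pi0)) if pi1 < 1 else 0.0
        # pi1 == 0 with k == 0 (or pi1 == 1 with k == n) contributes nothing
    stat = max(0.0, 2.0 * stat)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult("likelihood ratio (chi-square, 1 df)", stat, p, pi1, df=1)


def odds_fold(p: float) -> float:
    """Fold difference between alleles implied by a proportion: p / (1 - p)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"proportion must be in (0, 1), got {p}")
    return p / (1.0 - p)


def allelic_ratio(n_a: int, n_b: int, *, haldane: bool = False) -> float:
    """Allele-count ratio n_a / n_b; opt-in Haldane +0.5 correction for zeros."""
    if haldane:
        return (n_a + 0.5) / (n_b + 0.5)
    if n_a == 0 or n_b == 0:
        raise ValueError(
            "zero allele count makes the ratio degenerate; pass haldane=True to apply "
            "the +0.5 Haldane correction explicitly"
        )
    return n_a / n_b


def _t_one_sample(values: np.ndarray, method: str, estimate: float | None = None) -> TestResult:
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    est = mean if estimate is None else estimate
    if sd == 0.0:
        if mean == 0.0:
            warnings.warn(f"{method}: zero-variance, zero-mean input; returning p=1", stacklevel=3)
            return TestResult(method, 0.0, 1.0, est, df=n - 1, degenerate=True)
        warnings.warn(f"{method}: zero-variance, nonzero-mean input; unbounded statistic", stacklevel=3)
        return TestResult(method, math.copysign(math.inf, mean), 0.0, est, df=n - 1, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return TestResult(method, t, min(1.0, p), est, df=n - 1)


def ase_paired_test(pairs: list[tuple[float, float]]) -> TestResult:
    """Paired t-test of log2 allele ratios, cDNA (RNA) vs genomic DNA.

    ``pairs`` holds per-sample (rna_ratio, dna_ratio) of allele-supporting tag
    counts; the test compares log2(rna_ratio) - log2(dna_ratio) against zero.
    Ratios must be finite and positive — build them with
    :func:`allelic_ratio`, which makes zero-count handling explicit.
    """
    if len(pairs) < 2:
        raise ValueError("paired test requires at least 2 sample pairs")
    arr = np.asarray(pairs, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(
            "ratios must be positive and finite; for zero allele counts opt into the "
            "Haldane +0.5 correction via allelic_ratio(..., haldane=True)"
        )
    diffs = np.log2(arr[:, 0]) - np.log2(arr[:, 1])
    return _t_one_sample(diffs, "paired t on log2 ratios (two-sided)")


def one_sample_log2_test(values: list[float]) -> TestResult:
    """One-sample t-test of log2(fold changes) against zero."""
    if len(values) < 2:
        raise ValueError("one-sample test requires at least 2 values")
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("fold changes must be positive and finite")
    return _t_one_sample(np.log2(arr), "one-sample t on log2 fold change (two-sided)")


def welch_two_sample_test(group_a: list[float], group_b: list[float]) -> TestResult:
    """Welch's two-sample t-test (Satterthwaite degrees of freedom)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    est = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if est == 0.0:
            warnings.warn("Welch test: identical zero-variance groups; returning p=1", stacklevel=2)
            return TestResult("Welch t (two-sided)", 0.0, 1.0, est, df=float(a.size + b.size - 2), degenerate=True)
        warnings.warn("Welch test: zero-variance groups with different means", stacklevel=2)
        return TestResult("Welch t (two-sided)", math.copysign(math.inf, est), 0.0, est, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("Welch t (two-sided)", float(res.statistic), float(res.pvalue), est, df=float(res.df))
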