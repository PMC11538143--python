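"""Rank-based and descriptive statistics used throughout the study.

All inferential statistics here operate on mid-ranks (tied observations get
the mean of the rank positions they span), which makes them invariant under
strictly increasing transforms of the data — the property that lets yearly
search totals correlate identically with any two strictly rising indicator
columns.

Conventions, chosen to match how desk studies in this area are typically
computed (spreadsheet + online calculators):

* Spearman's rho is the product-moment correlation of the two mid-rank
  vectors; with no ties this reduces exactly to ``1 - 6*sum(d^2)/(n(n^2-1))``.
  The two-tailed p uses the t approximation ``t = rho*sqrt((n-2)/(1-rho^2))``
  with ``n-2`` degrees of freedom; ``|rho| = 1`` maps to ``p = 0``.
* The one-sample Kolmogorov–Smirnov normality screen fits the normal by the
  sample mean and the n−1 standard deviation, takes the ECDF supremum on
  both sides of every jump, and converts ``sqrt(n)*D`` through the
  asymptotic Kolmogorov distribution (no Lilliefors small-sample
  correction).
* Kruskal–Wallis uses pooled mid-ranks with the standard tie-correction
  divisor ``1 - sum(t^3 - t)/(N^3 - N)`` and a chi-square (k−1 df) p.
* The mode is the exact-value mode with ties broken by first occurrence in
  input order, the behaviour of spreadsheet ``MODE`` on repeated counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateSequenceError, DomainError

__all__ = [
    "CorrelationResult",
    "TestResult",
    "SummaryStats",
    "midranks",
    "spearman",
    "kruskal_wallis",
    "ks_normal",
    "summarize",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A rank correlation with its significance and variance-explained share.

    ``variance_pct`` is ``100 * rho**2``, the percentage of the dependent
    variable's (rank) variance explained by the independent variable.
    """

    rho: float
    n: int
    p_two_tailed: float
    variance_pct: float

    def rounded(self) -> "CorrelationResult":
        """Copy at report precision: rho 5 d.p., p 5 d.p., variance 2 d.p."""
        return CorrelationResult(
            rho=round(self.rho, 5),
            n=self.n,
            p_two_tailed=round(self.p_two_tailed, 5),
            variance_pct=round(self.variance_pct, 2),
        )


@dataclass(frozen=True)
class TestResult:
    """Statistic/p pair with a plain-language verdict (empty when n/a)."""

    statistic: float
    p_value: float
    verdict: str = ""


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    std: float
    median: float
    mode: float


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks 1..n; tied values share the mean of the ranks they span."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot rank an empty sequence")
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(arr.size, dtype=float)
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # mean of positions i..j, 1-based
        i = j + 1
    return ranks


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with two-tailed t-approximation p-value."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise DomainError(f"length mismatch: {xa.size} vs {ya.size}")
    n = int(xa.size)
    if n < 3:
        raise DomainError(f"need n >= 3 for a rank correlation, got {n}")
    rx, ry = midranks(xa), midranks(ya)
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateSequenceError("degenerate sequence: zero rank variance")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (rx.std() * ry.std()))
    rho = max(-1.0, min(1.0, rho))
    if abs(abs(rho) - 1.0) < 1e-12:  # snap perfect rank agreement to +/-1
        rho = math.copysign(1.0, rho)
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * _sps.t.sf(abs(t), n - 2)
        p = max(0.0, min(1.0, p))
    return CorrelationResult(rho=rho, n=n, p_two_tailed=p, variance_pct=100.0 * rho * rho)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H across >= 2 groups, tie-corrected, chi-square p."""
    if len(groups) < 2:
        raise DomainError(f"need at least 2 groups, got {len(groups)}")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise DomainError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = pooled.size
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        r_sum = ranks[start : start + size].sum()
        h += r_sum * r_sum / size
        start += size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    divisor = 1.0 - tie_term / (n_total**3 - n_total)
    if divisor == 0.0:  # every pooled value identical
        return TestResult(statistic=0.0, p_value=1.0, verdict="no separation")
    h = max(0.0, h / divisor)
    df = len(groups) - 1
    p = float(_sps.chi2.sf(h, df))
    verdict = (
        "statistically significant differences between groups"
        if p < 0.05
        else "no statistically significant differences between groups"
    )
    return TestResult(statistic=h, p_value=p, verdict=verdict)


def ks_normal(values: Sequence[float]) -> TestResult:
    """One-sample K-S screen against a normal fitted by sample mean/std.

    D is the ECDF supremum distance evaluated on both sides of every jump;
    the p-value comes from the asymptotic Kolmogorov distribution at
    ``sqrt(n)*D``.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 3:
        raise DomainError(f"need n >= 3 for the normality screen, got {n}")
    std = arr.std(ddof=1)
    if std == 0:
        raise DomainError("zero variance: normality screen undefined")
    cdf = _sps.norm.cdf((arr - arr.mean()) / std)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d = float(np.max(np.maximum(ecdf_hi - cdf, cdf - ecdf_lo)))
    p = float(_sps.kstwobign.sf(math.sqrt(n) * d))
    p = max(0.0, min(1.0, p))
    verdict = (
        "statistically significantly different from normal distribution"
        if p < 0.05
        else "not statistically significantly different from normal distribution"
    )
    return TestResult(statistic=d, p_value=p, verdict=verdict)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, n−1 standard deviation, median and first-encountered mode."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarise an empty sequence")
    counts = Counter(arr.tolist())
    top = max(counts.values())
    mode = next(v for v in arr.tolist() if counts[v] == top)
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        mean=float(arr.mean()),
        std=std,
        median=float(np.median(arr)),
        mode=float(mode),
    )
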