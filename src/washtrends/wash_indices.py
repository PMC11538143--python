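"""The study's defined quantities: extraction stability, yearly totals,
the composite disaster-risk index, the relative-interest share, and the
survey sample size.

Five closed-form quantities drive the analysis:

* **COV** — per-month extraction stability, ``100*|value - average|/average``
  where ``average`` is the mean of the two extraction occasions.  With
  exactly two occasions this is the same number whichever occasion's value
  is plugged in, and equals ``100*|v1 - v2|/(v1 + v2)``.
* **YTWRMT** — the yearly total of the WASH-related monthly volumes summed
  over all terms and all 12 months of a calendar year.
* **RDWDR** — under-five mortality divided by a weighted mean of the three
  access percentages (water 0.45, sanitation 0.45, hand-washing 0.10),
  scaled by 100; interpreted as disaster risk per unit WASH improvement.
  A missing hand-washing percentage counts as zero *only here*.
* **PTSSA** — the share (%) of worldwide searches attributable to the WASH
  terms once both sides are normalised by population and internet
  penetration.
* **NSS** — the classical ``ceil(z^2 p(1-p)/e^2)`` survey sample size, with
  no finite-population correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _sps

from .errors import CoverageError, DomainError, StructuralError, UndefinedCOVError
from .fixtures_io import (
    MISSING,
    AnnualIndicatorRecord,
    GlobalContextRecord,
    MonthlySeries,
)

__all__ = [
    "ExtractionPair",
    "RdwdrWeights",
    "MonthlyCOV",
    "cov_monthly",
    "cov_summary",
    "ytwrmt",
    "rdwdr",
    "ptssa",
    "necessary_sample_size",
]


@dataclass(frozen=True)
class ExtractionPair:
    """Two extractions of the same term's series, taken on separate occasions.

    The underlying monthly volumes are re-estimated by the search engine on
    a sliding basis, so two extractions of the same window disagree
    slightly; the per-month ``average`` of the two occasions is the COV
    denominator.
    """

    first: MonthlySeries
    second: MonthlySeries

    def __post_init__(self):
        a, b = self.first, self.second
        if a.term != b.term:
            raise StructuralError(f"term mismatch: {a.term!r} vs {b.term!r}")
        if (a.start_year, a.start_month) != (b.start_year, b.start_month):
            raise StructuralError(f"calendar anchor mismatch for {a.term!r}")
        if len(a) != len(b):
            raise StructuralError(f"length mismatch for {a.term!r}")

    @property
    def term(self) -> str:
        return self.first.term

    @property
    def average(self) -> np.ndarray:
        """Per-month mean of the two occasions."""
        return (np.asarray(self.first.values, float) + np.asarray(self.second.values, float)) / 2.0


@dataclass(frozen=True)
class RdwdrWeights:
    """Weights of the composite index denominator; must sum to one."""

    w_water: float = 0.45
    w_sanitation: float = 0.45
    w_handwash: float = 0.10
    scale: float = 100.0

    def __post_init__(self):
        total = self.w_water + self.w_sanitation + self.w_handwash
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise DomainError(f"weights must sum to 1, got {total}")


@dataclass(frozen=True)
class MonthlyCOV:
    """Per-month COV percentages; NaN where the month was undefined.

    ``undefined_months`` lists the 1-based month indices at which both
    extractions were zero, so undefined months are reported rather than
    silently dropped.
    """

    term: str
    values: np.ndarray
    undefined_months: tuple

    @property
    def defined(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


def cov_monthly(pair: ExtractionPair) -> MonthlyCOV:
    """Per-month extraction-stability COV, ``100*|value - average|/average``.

    Months where both occasions are zero have no defined COV; if *every*
    month is such, an :class:`~washtrends.errors.UndefinedCOVError` is
    raised, otherwise the undefined months are carried in the result.
    """
    v1 = np.asarray(pair.first.values, dtype=float)
    avg = pair.average
    undefined = avg == 0.0
    if undefined.all():
        raise UndefinedCOVError((np.flatnonzero(undefined) + 1).tolist())
    values = np.full(avg.size, np.nan)
    ok = ~undefined
    values[ok] = 100.0 * np.abs(v1[ok] - avg[ok]) / avg[ok]
    return MonthlyCOV(
        term=pair.term,
        values=values,
        undefined_months=tuple((np.flatnonzero(undefined) + 1).tolist()),
    )


def cov_summary(pair: ExtractionPair) -> Tuple[float, float]:
    """Mean and n−1 std of the defined monthly COV values ("22 ± 6"-style)."""
    cov = cov_monthly(pair)
    defined = cov.defined
    if defined.size == 0:
        raise DomainError(f"no defined monthly COV for {pair.term!r}")
    std = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    return float(defined.mean()), std


def ytwrmt(series: Sequence[MonthlySeries], year: int, *, partial: bool = False) -> int:
    """Yearly total search volume over all terms for one calendar year.

    Every series must cover all 12 months of ``year`` unless ``partial``
    explicitly allows summing over whatever months are present.
    """
    if not series:
        raise DomainError("no series given")
    total = 0
    for s in series:
        chunk = s.year_slice(year)
        if len(chunk) < 12 and not partial:
            raise CoverageError(
                f"series {s.term!r} covers only {len(chunk)}/12 months of {year}"
            )
        total += sum(chunk)
    return total


def rdwdr(record: AnnualIndicatorRecord, weights: RdwdrWeights = RdwdrWeights()) -> float:
    """Composite disaster-risk index for one year's record.

    Missing hand-washing access is substituted by zero here (and only
    here), following the source-table footnote convention.
    """
    athwf = 0.0 if record.athwf is MISSING else record.athwf
    denom = (
        weights.w_water * record.atbw
        + weights.w_sanitation * record.atbs
        + weights.w_handwash * athwf
    )
    if denom <= 0:
        raise DomainError(f"non-positive access denominator in {record.year}")
    return weights.scale * record.mcufry / denom


def ptssa(record: GlobalContextRecord) -> float:
    """Share (%) of normalised worldwide searches held by the WASH terms."""
    denom = record.tgsgy * record.tpsa * record.psapia
    if denom <= 0:
        raise DomainError(f"non-positive denominator component in {record.year}")
    return 100.0 * record.ytwrmt * record.twp * record.pwpia / denom


def necessary_sample_size(
    confidence: float = 0.95,
    margin: float = 0.05,
    proportion: float = 0.5,
    population: Optional[int] = None,
) -> Tuple[int, Optional[float]]:
    """Survey sample size ``ceil(z^2 p(1-p)/e^2)`` and its population share.

    ``z`` is the exact two-sided normal quantile (1.96 at 95% to the usual
    two decimals — both give the same integer here).  No finite-population
    correction is applied.  When ``population`` is given, the second return
    value is ``100*n/population`` rounded to 4 d.p., else ``None``.
    """
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    if not 0 < margin < 1:
        raise DomainError(f"margin must be in (0, 1), got {margin}")
    if not 0 <= proportion <= 1:
        raise DomainError(f"proportion must be in [0, 1], got {proportion}")
    z = _sps.norm.ppf(0.5 + confidence / 2.0)
    n = math.ceil(z * z * proportion * (1.0 - proportion) / (margin * margin))
    if population is None:
        return n, None
    if population <= 0:
        raise DomainError(f"population must be positive, got {population}")
    return n, round(100.0 * n / population, 4)
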