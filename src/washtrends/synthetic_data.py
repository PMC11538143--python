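"""Seeded synthetic data with the statistical structure the study assumes.

The original monthly extractions were never deposited, so testable inputs
are emulated instead: per-term monthly count series follow a linear trend
plus additive Gaussian noise, rounded and clamped at zero; a second
"extraction occasion" applies a relative Gaussian jitter to each month;
annual indicator tables follow logistic access curves, exponential
mortality decay, an initial missing block for hand-washing access, and a
yearly search total aggregated from the generated monthly series.

Determinism: one ``seed`` governs everything.  Each stream (term series,
extraction jitter, indicator table) draws from its own child generator
derived deterministically from the seed and a stable stream key, so
regenerating one piece never perturbs another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

from .errors import DomainError
from .fixtures_io import MISSING, AnnualIndicatorRecord, MonthlySeries
from .wash_indices import ExtractionPair, ytwrmt as _ytwrmt

__all__ = [
    "TermSpec",
    "LogisticCurve",
    "SyntheticConfig",
    "gen_monthly_series",
    "gen_extraction_pair",
    "gen_indicator_table",
]


@dataclass(frozen=True)
class TermSpec:
    """Linear-trend model for one term: intercept + slope*month + noise."""

    term: str
    intercept: float
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class LogisticCurve:
    """Logistic trajectory between two levels over the study years.

    ``midpoint`` is the 0-based year offset of the inflection; ``rate`` is
    the steepness per year.
    """

    start: float
    end: float
    midpoint: float
    rate: float

    def at(self, year_offset: int) -> float:
        return self.start + (self.end - self.start) / (
            1.0 + math.exp(-self.rate * (year_offset - self.midpoint))
        )


# Nine terms calibrated to the observed per-term monthly statistics over a
# 222-month window: for each term the (intercept, slope, noise_sd) triple
# solves mean = intercept + slope*mean(t), var = slope^2*var(t) + noise^2
# and slope*sd(t)/noise = rho/sqrt(1 - rho^2) for the observed mean,
# standard deviation and trend correlation.  Negative intercepts (with the
# clamp at zero) emulate terms whose early counts sit at zero.
DEFAULT_TERMS: Tuple[TermSpec, ...] = (
    TermSpec("sanitation", 1409.0, 3.20, 770.0),
    TermSpec("wash", 246.0, 16.04, 273.0),
    TermSpec("diarrhoea", 10835.0, 174.0, 9801.0),
    TermSpec("hygiene", 5043.0, -6.18, 1284.0),
    TermSpec("water", 17126.0, 51.8, 3441.0),
    TermSpec("sewage", 2560.0, -4.10, 988.0),
    TermSpec("greywater", 4331.0, 7.82, 6980.0),
    TermSpec("pit_latrine", -169.0, 5.83, 561.0),
    TermSpec("toilet", 4548.0, 59.2, 2750.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults emulate the study window (222 months from January 2004, nine
    terms) and indicator shapes in the observed ranges: basic-water access
    rising from the high 80s toward the mid 90s (%), sanitation from the
    low 60s toward ~80%, hand-washing access missing for the first eight
    years then in the 40–60% band, and under-five mortality decaying
    exponentially from ~78 toward ~32 deaths per 1000 live births.
    """

    terms: Tuple[TermSpec, ...] = DEFAULT_TERMS
    n_months: int = 222
    start_year: int = 2004
    start_month: int = 1
    jitter_scale: float = 0.05
    n_years: int = 17
    water_curve: LogisticCurve = LogisticCurve(86.6, 94.5, 8.0, 0.15)
    sanitation_curve: LogisticCurve = LogisticCurve(62.5, 80.0, 8.0, 0.18)
    handwash_curve: LogisticCurve = LogisticCurve(40.0, 62.0, 10.0, 0.35)
    handwash_missing_years: int = 8
    mortality_start: float = 78.0
    mortality_decay: float = 0.055
    seed: int = 0

    def __post_init__(self):
        if self.n_months < 12:
            raise DomainError(f"n_months must be >= 12, got {self.n_months}")
        if not self.terms:
            raise DomainError("at least one term required")
        if self.jitter_scale < 0 or any(t.noise_sd < 0 for t in self.terms):
            raise DomainError("noise and jitter scales must be >= 0")
        if not 1 <= self.start_month <= 12:
            raise DomainError(f"start_month outside 1..12: {self.start_month}")
        if self.n_years < 5:
            raise DomainError(f"n_years must be >= 5, got {self.n_years}")
        if self.handwash_missing_years < 0:
            raise DomainError("handwash_missing_years must be >= 0")
        if self.mortality_decay < 0 or self.mortality_start < 0:
            raise DomainError("mortality parameters must be >= 0")


def _rng(seed: int, stream: str, sub: str = "") -> np.random.Generator:
    # stable child stream: seed plus CRC32 keys of the stream labels
    key = (zlib.crc32(stream.encode()), zlib.crc32(sub.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def gen_monthly_series(
    config: SyntheticConfig, *, n_months: int = None
) -> list:
    """Generate one noisy linear-trend series per configured term.

    ``value_t = round(max(0, intercept + slope*t + eps_t))`` with Gaussian
    ``eps_t``; identical seed implies identical output.
    """
    months = config.n_months if n_months is None else n_months
    t = np.arange(1, months + 1, dtype=float)
    out = []
    for spec in config.terms:
        rng = _rng(config.seed, "monthly", spec.term)
        eps = rng.normal(0.0, spec.noise_sd, size=months) if spec.noise_sd else 0.0
        raw = spec.intercept + spec.slope * t + eps
        values = np.round(np.maximum(raw, 0.0)).astype(int)
        out.append(
            MonthlySeries(
                term=spec.term,
                start_year=config.start_year,
                start_month=config.start_month,
                values=tuple(int(v) for v in values),
            )
        )
    return out


def gen_extraction_pair(series: MonthlySeries, config: SyntheticConfig) -> ExtractionPair:
    """Simulate a second extraction occasion by relative Gaussian jitter.

    ``second_t = round(max(0, value_t * (1 + eta_t)))`` with
    ``eta_t ~ N(0, jitter_scale)``; zero jitter reproduces the series
    exactly, so every COV is zero.
    """
    rng = _rng(config.seed, "jitter", series.term)
    v = np.asarray(series.values, dtype=float)
    if config.jitter_scale == 0:
        second = v.copy()
    else:
        eta = rng.normal(0.0, config.jitter_scale, size=v.size)
        second = np.round(np.maximum(v * (1.0 + eta), 0.0))
    twin = MonthlySeries(
        term=series.term,
        start_year=series.start_year,
        start_month=series.start_month,
        values=tuple(int(x) for x in second),
    )
    return ExtractionPair(first=series, second=twin)


def gen_indicator_table(config: SyntheticConfig) -> list:
    """Generate an annual indicator table with the study's shapes.

    Access percentages follow their logistic curves, mortality decays
    exponentially, hand-washing access is missing for the configured
    initial block, and the yearly search total is aggregated from a
    generated monthly panel covering the full span of years.
    """
    months_needed = config.n_years * 12
    series = gen_monthly_series(config, n_months=months_needed)
    records = []
    for i in range(config.n_years):
        year = config.start_year + i
        athwf = (
            MISSING
            if i < config.handwash_missing_years
            else min(100.0, max(0.0, config.handwash_curve.at(i)))
        )
        records.append(
            AnnualIndicatorRecord(
                year=year,
                ytwrmt=_ytwrmt(series, year),
                atbw=min(100.0, config.water_curve.at(i)),
                atbs=min(100.0, config.sanitation_curve.at(i)),
                athwf=athwf,
                mcufry=config.mortality_start * math.exp(-config.mortality_decay * i),
            )
        )
    return records
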