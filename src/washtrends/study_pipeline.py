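"""End-to-end orchestration of the study's analyses.

Three entry points:

* :func:`term_summary` — the per-term descriptive table: summary
  statistics, extraction-stability COV (when a second extraction is
  supplied), the monotone-trend rank correlation against the 1-based month
  index, a normality screen, and one pooled Kruskal–Wallis test across
  terms.
* :func:`indicator_study` — rank correlations between the yearly search
  total and each annual indicator.  The hand-washing access column is
  correlated only over its reported years (missing years excluded); the
  composite index is recomputed from the indicator columns with the
  zero-substitution convention before correlating.
* :func:`build_report` — deterministic delimited + narrative report files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

from .errors import DomainError
from .fixtures_io import (
    MISSING,
    AnnualIndicatorRecord,
    MonthlySeries,
)
from .rank_stats import (
    CorrelationResult,
    SummaryStats,
    TestResult,
    kruskal_wallis,
    ks_normal,
    spearman,
    summarize,
)
from .wash_indices import ExtractionPair, RdwdrWeights, cov_summary, rdwdr

__all__ = [
    "MissingPolicy",
    "TermRow",
    "TermReport",
    "IndicatorStudyReport",
    "term_summary",
    "indicator_study",
    "build_report",
]

INDICATORS = ("atbw", "atbs", "athwf", "mcufry", "rdwdr")


@dataclass(frozen=True)
class MissingPolicy:
    """How missing hand-washing access enters the correlation study.

    ``athwf="exclude"`` correlates only the reported years (the default —
    the only policy that reproduces the published coefficient);
    ``athwf="zero"`` substitutes zero everywhere.  Inside the composite
    index, missing is always zero-substituted, per the source-table
    footnote.
    """

    athwf: str = "exclude"
    weights: RdwdrWeights = field(default_factory=RdwdrWeights)

    def __post_init__(self):
        if self.athwf not in ("exclude", "zero"):
            raise DomainError(f"unknown athwf policy {self.athwf!r}")


@dataclass(frozen=True)
class TermRow:
    term: str
    stats: SummaryStats
    trend: CorrelationResult
    normality: TestResult
    cov: Optional[Tuple[float, float]] = None  # (mean, std) of monthly COV


@dataclass(frozen=True)
class TermReport:
    rows: Tuple[TermRow, ...]
    kruskal: TestResult


@dataclass(frozen=True)
class IndicatorStudyReport:
    """Per-indicator correlation of the yearly total with each indicator."""

    correlations: Dict[str, CorrelationResult]
    policy: MissingPolicy
    years_used: Dict[str, Tuple[int, ...]]


def term_summary(
    series: Sequence[MonthlySeries],
    pairs: Optional[Sequence[ExtractionPair]] = None,
) -> TermReport:
    """Descriptive per-term table plus one pooled across-terms rank test.

    The trend correlation uses the 1-based month index as the independent
    variable; the Kruskal–Wallis test pools every term's monthly volumes.
    """
    if not series:
        raise DomainError("no series given")
    pair_by_term = {p.term: p for p in pairs} if pairs else {}
    unknown = set(pair_by_term) - {s.term for s in series}
    if unknown:
        raise DomainError(f"extraction pairs for unknown terms: {sorted(unknown)}")
    rows = []
    for s in series:
        values = list(s.values)
        cov = None
        if s.term in pair_by_term:
            cov = cov_summary(pair_by_term[s.term])
        rows.append(
            TermRow(
                term=s.term,
                stats=summarize(values),
                trend=spearman(list(s.month_index), values),
                normality=ks_normal(values),
                cov=cov,
            )
        )
    kw = kruskal_wallis([list(s.values) for s in series])
    return TermReport(rows=tuple(rows), kruskal=kw)


def indicator_study(
    records: Sequence[AnnualIndicatorRecord],
    policy: MissingPolicy = MissingPolicy(),
) -> IndicatorStudyReport:
    """Correlate the yearly search total with each annual indicator.

    The composite index is recomputed from the record columns (never taken
    from a carried report column), with missing hand-washing access
    zero-substituted inside the index only.  For the hand-washing column
    itself the default policy drops missing years.  Each correlation needs
    at least three usable years.
    """
    if len(records) < 3:
        raise DomainError("need at least 3 annual records")
    results: Dict[str, CorrelationResult] = {}
    years_used: Dict[str, Tuple[int, ...]] = {}
    for name in INDICATORS:
        if name == "rdwdr":
            pairs = [(r.ytwrmt, rdwdr(r, policy.weights), r.year) for r in records]
        elif name == "athwf" and policy.athwf == "exclude":
            pairs = [(r.ytwrmt, r.athwf, r.year) for r in records if r.athwf is not MISSING]
        elif name == "athwf":
            pairs = [
                (r.ytwrmt, 0.0 if r.athwf is MISSING else r.athwf, r.year)
                for r in records
            ]
        else:
            pairs = [(r.ytwrmt, getattr(r, name), r.year) for r in records]
        if len(pairs) < 3:
            raise DomainError(
                f"indicator {name!r}: only {len(pairs)} usable years after policy"
            )
        x, y, years = zip(*pairs)
        results[name] = spearman(x, y)
        years_used[name] = tuple(years)
    return IndicatorStudyReport(correlations=results, policy=policy, years_used=years_used)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def build_report(
    reports: Sequence[Union[TermReport, IndicatorStudyReport]],
    destination: Union[str, Path],
) -> list:
    """Write delimited tables plus a plain-text narrative of verdicts.

    Output is deterministic: identical inputs produce byte-identical
    files.  Returns the list of written paths.
    """
    if not reports:
        raise DomainError("no reports to write")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    narrative = []
    for report in reports:
        if isinstance(report, TermReport):
            path = dest / "term_summary.tsv"
            _write_term_table(report, path)
            written.append(path)
            narrative.append(
                "Across-term Kruskal-Wallis: H = "
                f"{report.kruskal.statistic:.3f}, p = {report.kruskal.p_value:.5f} "
                f"({report.kruskal.verdict})."
            )
            for row in report.rows:
                narrative.append(
                    f"Term {row.term!r}: monthly volumes are {row.normality.verdict}; "
                    f"trend rho = {row.trend.rho:.5f} (p = {row.trend.p_two_tailed:.5f}, "
                    f"variance explained {row.trend.variance_pct:.2f}%)."
                )
        elif isinstance(report, IndicatorStudyReport):
            path = dest / "indicator_correlations.tsv"
            _write_indicator_table(report, path)
            written.append(path)
            for name in INDICATORS:
                c = report.correlations[name].rounded()
                verdict = "significant" if c.p_two_tailed < 0.05 else "not significant"
                narrative.append(
                    f"Yearly total vs {name.upper()}: rho = {c.rho:.5f} on n = {c.n} "
                    f"years, p = {c.p_two_tailed:.5f} ({verdict}); "
                    f"variance explained {c.variance_pct:.2f}%."
                )
        else:
            raise DomainError(f"unknown report object {type(report).__name__}")
    narrative_path = dest / "narrative.txt"
    narrative_path.write_text("\n".join(narrative) + "\n", encoding="utf-8")
    written.append(narrative_path)
    return written


def _write_term_table(report: TermReport, path: Path) -> None:
    header = [
        "term", "average", "std", "mode", "median", "cov_mean", "cov_std",
        "spearman_rho", "variance_pct", "p", "ks_D", "ks_p", "distribution",
    ]
    lines = ["\t".join(header)]
    for row in report.rows:
        trend = row.trend.rounded()
        cov_mean = f"{row.cov[0]:.1f}" if row.cov else ""
        cov_std = f"{row.cov[1]:.1f}" if row.cov else ""
        lines.append(
            "\t".join(
                [
                    row.term,
                    f"{row.stats.mean:.0f}",
                    f"{row.stats.std:.0f}",
                    f"{row.stats.mode:.0f}",
                    f"{row.stats.median:.0f}",
                    cov_mean,
                    cov_std,
                    f"{trend.rho:.5f}",
                    f"{trend.variance_pct:.2f}",
                    f"{trend.p_two_tailed:.5f}",
                    f"{row.normality.statistic:.5f}",
                    f"{row.normality.p_value:.5f}",
                    row.normality.verdict,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_indicator_table(report: IndicatorStudyReport, path: Path) -> None:
    lines = ["\t".join(["indicator", "rho", "n", "p", "variance_pct", "years"])]
    for name in INDICATORS:
        c = report.correlations[name].rounded()
        years = report.years_used[name]
        span = f"{years[0]}-{years[-1]}" if years else ""
        lines.append(
            "\t".join(
                [name, f"{c.rho:.5f}", str(c.n), f"{c.p_two_tailed:.5f}",
                 f"{c.variance_pct:.2f}", span]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
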