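"""Delimited-table input/output and packaged reference tables.

The pipeline's raw signal is a set of monthly search-volume series (one
integer count per term per calendar month) and two kinds of annual tables:
WASH-indicator records (access percentages, under-five mortality, yearly
search totals) and global-context records (world population, worldwide
search totals, internet penetration).  Published versions of these tables
use a few numeric dialects — space-grouped thousands (``862 860``),
typeset scientific notation (``7.95 × 10^10^``) and an explicit
"Not reported; 0" marker for missing hand-washing coverage — which
:func:`parse_number` normalises.

Missingness is first class: a missing cell becomes ``None``, never ``0``.
Zero-substitution for missing hand-washing access happens only inside the
composite-index computation (see :mod:`washtrends.wash_indices`), mirroring
the footnote convention of the source tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, StructuralError

__all__ = [
    "MISSING",
    "Dialect",
    "MonthlySeries",
    "AnnualIndicatorRecord",
    "GlobalContextRecord",
    "parse_number",
    "format_number",
    "read_monthly_series",
    "write_monthly_series",
    "read_indicator_table",
    "write_indicator_table",
    "load_fixture",
]

#: Sentinel for a missing (not-reported) value.  Distinct from zero.
MISSING = None

#: Cell text understood (and emitted) for a missing value.
_MISSING_TOKEN = "Not reported; 0"

# "7.95 × 10^10^" with optional footnote daggers and either × or x.
_SCI_RE = re.compile(r"^\s*([0-9]+(?:[.,][0-9]+)?)\s*[×x]\s*10\^?(-?[0-9]+)\^?\s*$")


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect options.

    separator: field separator of the file (tab or comma).
    decimal: decimal mark used inside numeric cells.
    """

    separator: str = "\t"
    decimal: str = "."


def parse_number(
    token: str,
    *,
    decimal: str = ".",
    row: Optional[int] = None,
    column: Optional[str] = None,
) -> Optional[float]:
    """Parse one numeric cell, normalising the published dialects.

    Handles plain decimals, space-grouped thousands (normal or no-break
    space), typeset scientific notation ``a × 10^b^`` and the literal
    missing-data marker ``"Not reported; 0"`` (with or without trailing
    footnote symbols), which maps to :data:`MISSING`.

    Raises :class:`FormatError` naming the row/column for anything else.
    """
    if not isinstance(token, str) or not token.strip():
        raise FormatError(_cell_msg("empty cell", row, column))
    text = token.replace(" ", " ").replace(" ", " ").strip()
    # strip footnote daggers/markers that may trail the cell
    text = text.rstrip("*†‡§¶ ")
    if text.startswith("Not reported"):
        return MISSING
    if decimal != ".":
        text = text.replace(decimal, ".")
    m = _SCI_RE.match(text)
    if m:
        return float(m.group(1).replace(",", ".")) * 10.0 ** int(m.group(2))
    compact = text.replace(" ", "")
    try:
        return float(compact)
    except ValueError:
        raise FormatError(_cell_msg(f"unparseable token {token!r}", row, column)) from None


def _cell_msg(msg: str, row: Optional[int], column: Optional[str]) -> str:
    where = []
    if row is not None:
        where.append(f"row {row}")
    if column is not None:
        where.append(f"column {column!r}")
    return f"{msg} ({', '.join(where)})" if where else msg


def format_number(value: Optional[float]) -> str:
    """Inverse of :func:`parse_number` for the canonical writer dialect."""
    if value is MISSING:
        return _MISSING_TOKEN
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


@dataclass(frozen=True)
class MonthlySeries:
    """One query term's ordered monthly search volumes, calendar anchored.

    ``month_index`` is 1-based: index 1 is the (start_year, start_month)
    month; with the study anchoring of January 2004 that makes index 222
    equal June 2022.
    """

    term: str
    start_year: int
    start_month: int
    values: tuple = field(default_factory=tuple)

    def __post_init__(self):
        values = tuple(int(v) for v in self.values)
        if any(v != float(raw) for v, raw in zip(values, self.values)):
            raise StructuralError(f"non-integral volume in series {self.term!r}")
        if len(values) < 1:
            raise StructuralError(f"series {self.term!r} is empty")
        if any(v < 0 for v in values):
            raise StructuralError(f"negative volume in series {self.term!r}")
        if not 1 <= self.start_month <= 12:
            raise StructuralError(f"start_month {self.start_month} outside 1..12")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def month_index(self) -> range:
        """1-based month positions (1 = first month, no gaps)."""
        return range(1, len(self.values) + 1)

    def months(self) -> Iterator[tuple]:
        """Yield (year, month) for each observation, in order."""
        year, month = self.start_year, self.start_month
        for _ in self.values:
            yield year, month
            month += 1
            if month > 12:
                month, year = 1, year + 1

    def year_slice(self, year: int) -> tuple:
        """The volumes falling inside calendar ``year`` (possibly partial)."""
        return tuple(v for (y, _), v in zip(self.months(), self.values) if y == year)

    def covers_year(self, year: int) -> bool:
        """True when all 12 months of ``year`` are observed."""
        return len(self.year_slice(year)) == 12


@dataclass(frozen=True)
class AnnualIndicatorRecord:
    """One calendar year of WASH indicators.

    ytwrmt: yearly total search volume across all WASH terms (count).
    atbw / atbs: % population with access to basic water / sanitation.
    athwf: % population with access to hand-washing facilities, or
        :data:`MISSING` for years with no reported value.
    mcufry: under-five mortality, deaths per 1000 live births.
    rdwdr: composite disaster-risk index as carried by the source table
        (kept separate from recomputed values so the two can be compared);
        ``None`` when the table carries no derived column.
    """

    year: int
    ytwrmt: float
    atbw: float
    atbs: float
    athwf: Optional[float]
    mcufry: float
    rdwdr: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.atbw <= 100 or not 0 <= self.atbs <= 100:
            raise StructuralError(f"access percentage outside [0, 100] in {self.year}")
        if self.athwf is not MISSING and not 0 <= self.athwf <= 100:
            raise StructuralError(f"athwf outside [0, 100] in {self.year}")
        if self.mcufry < 0 or self.ytwrmt < 0:
            raise StructuralError(f"negative count/rate in {self.year}")


@dataclass(frozen=True)
class GlobalContextRecord:
    """One calendar year of global denominators for the relative-interest share.

    tgsgy: total worldwide Google searches that year; twp / tpsa: world and
    South African population; pwpia / psapia: % of world / South African
    population using the internet; ptssa: the share of (population- and
    penetration-normalised) searches that the WASH terms represent, as
    carried by the source table; nss / nss_pct: necessary survey sample
    size and its percentage of the national population, as carried.
    """

    year: int
    ytwrmt: float
    tgsgy: float
    twp: float
    tpsa: float
    pwpia: float
    psapia: float
    ptssa: Optional[float] = None
    nss: Optional[int] = None
    nss_pct: Optional[float] = None

    def __post_init__(self):
        for name in ("ytwrmt", "tgsgy", "twp", "tpsa"):
            if getattr(self, name) <= 0:
                raise StructuralError(f"non-positive count {name} in {self.year}")
        for name in ("pwpia", "psapia"):
            if not 0 < getattr(self, name) <= 100:
                raise StructuralError(f"{name} outside (0, 100] in {self.year}")


# ---------------------------------------------------------------------------
# monthly series tables
# ---------------------------------------------------------------------------

def read_monthly_series(
    path: Union[str, Path], dialect: Dialect = Dialect()
) -> list:
    """Read a monthly-volume table: ``year``, ``month``, then one column per term.

    Rows must form a gapless, duplicate-free month sequence; row order is
    preserved and the first row anchors the calendar.
    """
    frame = pd.read_csv(path, sep=dialect.separator, dtype=str)
    cols = list(frame.columns)
    if cols[:2] != ["year", "month"]:
        raise StructuralError(
            f"expected leading 'year','month' columns, found {cols[:2]} in {path}"
        )
    terms = cols[2:]
    if not terms:
        raise StructuralError(f"no term columns in {path}")
    years = frame["year"].astype(int).tolist()
    months = frame["month"].astype(int).tolist()
    _check_month_sequence(years, months, path)
    series = []
    for term in terms:
        values = [
            parse_number(tok, decimal=dialect.decimal, row=i + 2, column=term)
            for i, tok in enumerate(frame[term])
        ]
        if any(v is MISSING for v in values):
            raise FormatError(f"missing volume in term column {term!r} of {path}")
        series.append(
            MonthlySeries(
                term=term,
                start_year=years[0],
                start_month=months[0],
                values=tuple(int(v) for v in values),
            )
        )
    return series


def _check_month_sequence(years, months, path) -> None:
    seen = set()
    for i in range(len(years)):
        if (years[i], months[i]) in seen:
            raise StructuralError(f"duplicate month {years[i]}-{months[i]:02d} in {path}")
        seen.add((years[i], months[i]))
        if i == 0:
            continue
        y, m = years[i - 1], months[i - 1] + 1
        if m > 12:
            y, m = y + 1, 1
        if (years[i], months[i]) != (y, m):
            raise StructuralError(
                f"month sequence gap after {years[i-1]}-{months[i-1]:02d} in {path}"
            )


def write_monthly_series(
    path: Union[str, Path],
    series: Sequence[MonthlySeries],
    dialect: Dialect = Dialect(),
) -> None:
    """Write aligned monthly series in the layout :func:`read_monthly_series` reads."""
    if not series:
        raise StructuralError("no series to write")
    anchor = (series[0].start_year, series[0].start_month, len(series[0]))
    for s in series[1:]:
        if (s.start_year, s.start_month, len(s)) != anchor:
            raise StructuralError("series are not calendar-aligned")
    table = {"year": [], "month": []}
    for year, month in series[0].months():
        table["year"].append(year)
        table["month"].append(month)
    for s in series:
        table[s.term] = list(s.values)
    pd.DataFrame(table).to_csv(path, sep=dialect.separator, index=False)


# ---------------------------------------------------------------------------
# annual indicator tables
# ---------------------------------------------------------------------------

_INDICATOR_COLS = ["year", "ytwrmt", "atbw", "atbs", "athwf", "mcufry", "rdwdr"]


def read_indicator_table(
    path: Union[str, Path], dialect: Dialect = Dialect()
) -> list:
    """Read an annual WASH-indicator table (one row per year)."""
    frame = pd.read_csv(path, sep=dialect.separator, dtype=str)
    missing_cols = [c for c in _INDICATOR_COLS[:-1] if c not in frame.columns]
    if missing_cols:
        raise StructuralError(f"indicator table {path} lacks columns {missing_cols}")
    records = []
    for i, row in frame.iterrows():
        cell = lambda col: parse_number(
            row[col], decimal=dialect.decimal, row=i + 2, column=col
        )
        rdwdr = cell("rdwdr") if "rdwdr" in frame.columns else None
        records.append(
            AnnualIndicatorRecord(
                year=int(row["year"]),
                ytwrmt=cell("ytwrmt"),
                atbw=cell("atbw"),
                atbs=cell("atbs"),
                athwf=cell("athwf"),
                mcufry=cell("mcufry"),
                rdwdr=rdwdr,
            )
        )
    years = [r.year for r in records]
    if sorted(set(years)) != years:
        raise StructuralError(f"years not strictly increasing in {path}")
    return records


def write_indicator_table(
    path: Union[str, Path],
    records: Sequence[AnnualIndicatorRecord],
    dialect: Dialect = Dialect(),
) -> None:
    """Write indicator records in the layout :func:`read_indicator_table` reads."""
    rows = []
    for r in records:
        rows.append(
            {
                "year": r.year,
                "ytwrmt": format_number(r.ytwrmt),
                "atbw": format_number(r.atbw),
                "atbs": format_number(r.atbs),
                "athwf": format_number(r.athwf),
                "mcufry": format_number(r.mcufry),
                "rdwdr": format_number(r.rdwdr) if r.rdwdr is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_INDICATOR_COLS).to_csv(
        path, sep=dialect.separator, index=False
    )


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture(name: str) -> list:
    """Load one of the packaged reference tables.

    ``"table2"`` — 17 annual WASH-indicator records (2004–2020), with the
    published composite-index column carried for golden comparisons.
    ``"table6"`` — 19 global-context records (2004–2022), with the
    published relative-share and sample-size columns carried.
    """
    if name not in ("table2", "table6"):
        raise LookupError(f"unknown fixture {name!r}; expected 'table2' or 'table6'")
    ref = resources.files("washtrends.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        if name == "table2":
            return read_indicator_table(path, Dialect(separator="\t"))
        return _read_global_table(path)


def _read_global_table(path: Union[str, Path]) -> list:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for i, row in frame.iterrows():
        cell = lambda col: parse_number(row[col], row=i + 2, column=col)
        nss_txt = row["nss"]
        try:
            nss_count, nss_pct = nss_txt.split("/")
        except ValueError:
            raise FormatError(
                _cell_msg(f"expected 'count/percent' cell, got {nss_txt!r}", i + 2, "nss")
            ) from None
        records.append(
            GlobalContextRecord(
                year=int(row["year"]),
                ytwrmt=cell("ytwrmt"),
                tgsgy=cell("tgsgy"),
                twp=cell("twp"),
                tpsa=cell("tpsa"),
                pwpia=cell("pwpia"),
                psapia=cell("psapia"),
                ptssa=cell("ptssa"),
                nss=int(nss_count),
                nss_pct=float(nss_pct),
            )
        )
    return records
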