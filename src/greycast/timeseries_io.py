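"""Reading, validating and writing annual count series.

The package works on labelled annual series of strictly positive counts
(deaths per calendar year).  Input is long-format CSV with a header and the
columns ``country, year, value`` (the value column may be named ``deaths``).
The six study series (Pakistan, India, China, Kenya, USA, Sweden;
cardiovascular deaths 2005-2019, originally compiled from Our World in Data)
ship with the package and are returned by :func:`load_study_series`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError, ValidationError, YearGapError

__all__ = [
    "AnnualSeries",
    "read_annual_series",
    "load_study_series",
    "write_report_table",
    "round_display",
]

_STUDY_DATA = "cvd_deaths_2005_2019.csv"
_STUDY_COUNTRIES = ("Pakistan", "India", "China", "Kenya", "USA", "Sweden")


@dataclass(frozen=True)
class AnnualSeries:
    """A labelled run of consecutive calendar years with positive annual counts.

    Parameters
    ----------
    label
        Series name, typically a country.
    years
        Strictly consecutive calendar years, ascending.
    values
        Annual counts, all strictly positive (units: events/year).
    """

    label: str
    years: tuple[int, ...] = field(repr=False)
    values: tuple[float, ...] = field(repr=False)

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise ValidationError(
                f"{self.label}: {len(years)} years but {len(values)} values"
            )
        if not years:
            raise ValidationError(f"{self.label}: empty series")
        for a, b in zip(years, years[1:]):
            if b != a + 1:
                raise YearGapError(
                    f"{self.label}: years must be consecutive, found {a} then {b}"
                )
        for y, v in zip(years, values):
            if not np.isfinite(v) or v <= 0:
                raise DomainError(
                    f"{self.label}: non-positive value {v} in year {y}"
                )

    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return self.years[0]

    @property
    def last_year(self) -> int:
        return self.years[-1]

    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def value_in(self, year: int) -> float:
        """Value for a calendar year (KeyError if outside the series)."""
        if not self.years[0] <= year <= self.years[-1]:
            raise KeyError(f"{self.label}: year {year} outside series")
        return self.values[year - self.years[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"country": self.label, "year": self.years, "value": self.values}
        )


def read_annual_series(
    path: str | Path | io.TextIOBase, format: str = "long"
) -> list[AnnualSeries]:
    """Read long-format CSV (``country,year,value``) into one series per country.

    Countries keep their order of first appearance; rows within a country are
    sorted by year before validation.  Malformed rows raise :class:`ParseError`
    with the offending 1-based line number; invariant violations (year gaps,
    duplicate years, non-positive values) raise the corresponding validation
    error instead of being silently repaired.
    """
    if format != "long":
        raise ValueError(f"unknown input format {format!r}")
    df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    value_col = next((c for c in ("value", "deaths", "count") if c in cols), None)
    if "country" not in cols or "year" not in cols or value_col is None:
        raise ParseError(
            f"expected columns country,year,value (or deaths); found {cols}"
        )

    records: dict[str, list[tuple[int, float, int]]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        country = row["country"]
        if pd.isna(country) or not str(country).strip():
            raise ParseError("missing country", line=line)
        country = str(country).strip()
        try:
            year = int(str(row["year"]).strip())
        except (TypeError, ValueError):
            raise ParseError(f"unparsable year {row['year']!r}", line=line) from None
        try:
            value = float(str(row[value_col]).strip().replace(",", ""))
        except (TypeError, ValueError):
            raise ParseError(
                f"unparsable value {row[value_col]!r}", line=line
            ) from None
        if value <= 0:
            raise DomainError(
                f"{country}: non-positive value {value} in year {year}"
            )
        records.setdefault(country, []).append((year, value, line))

    out = []
    for country, rows in records.items():
        rows.sort(key=lambda r: r[0])
        years = [r[0] for r in rows]
        for (a, _, _), (b, _, line) in zip(rows, rows[1:]):
            if b == a:
                raise YearGapError(f"{country}: duplicate year {b}")
            if b != a + 1:
                raise YearGapError(
                    f"{country}: missing year {a + 1} (gap before {b})"
                )
        out.append(
            AnnualSeries(country, tuple(years), tuple(r[1] for r in rows))
        )
    return out


def load_study_series() -> list[AnnualSeries]:
    """The six bundled study series (annual CVD deaths, 2005-2019).

    Values are the published original-data columns, transcribed digit for
    digit with thousands separators removed.  Cumulative totals and all
    derived quantities are recomputed by the pipeline rather than taken from
    the published tables.
    """
    ref = resources.files(__package__).joinpath("data").joinpath(_STUDY_DATA)
    with ref.open("r", encoding="utf-8") as fh:
        series = read_annual_series(fh)
    order = {name: i for i, name in enumerate(_STUDY_COUNTRIES)}
    series.sort(key=lambda s: order.get(s.label, len(order)))
    return series


def round_display(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, the convention used for display columns."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def write_report_table(
    records: pd.DataFrame | Iterable[dict], path: str | Path,
    display_columns: Sequence[str] | None = None,
) -> None:
    """Write result rows as CSV with stable column order.

    Floating-point columns are emitted at full ``repr`` precision and, for
    each column named in *display_columns* (default: every float column), a
    companion ``<name>_3dp`` column rounded half away from zero to three
    decimals is appended — the precision used by the published tables.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df = df.copy()
    if display_columns is None:
        display_columns = [
            c for c in df.columns if pd.api.types.is_float_dtype(df[c])
        ]
    for c in display_columns:
        df[f"{c}_3dp"] = [
            round_display(v) if pd.notna(v) else np.nan for v in df[c]
        ]
    df.to_csv(path, index=False)
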